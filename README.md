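# ringmetrics

Quantification of contractile-ring dynamics in live-cell fluorescence
movies of dividing cells.

During cytokinesis, a RhoA-dependent actomyosin ring assembles at the
cell equator and constricts to pull in the plasma membrane. Ring
regulators such as anillin, Ect2 and RhoA enrich at the equatorial
cortex, and the *breadth*, *level* and *timing* of that enrichment — and
how symmetrically the ring closes — differ between cell types. This
package reimplements, as a tested Python library, the measurement
procedures used in live-imaging studies of these questions, replacing
ad-hoc ImageJ macros and spreadsheets:

- **Preprocessing** — per-frame background subtraction (constant,
  percentile or background-ROI), bleach correction (ratio to the first
  frame, or single-exponential fit), and central-slice average
  Z-projection (2 slices for cortical scans, 6 for the central spindle).
- **Cortical linescans** — five-pixel-wide intensity profiles sampled at
  1 px arc spacing along a pole-to-pole cortex polyline (or a straight
  midzone line), registered to the furrow crossing, and normalized
  against the polar baseline (mean of the first or last 50 samples).
- **Per-cell statistics** — peak breadth
  `b = |{i : I_i ≥ I_base + c · (I_max − I_base)}|` counted over the
  contiguous above-cutoff run containing the peak (cutoff fraction
  `c` = 0.5 or 0.75; isolated off-peak pixels above the cutoff are
  excluded), in µm and as a fraction of cortical length; furrow/pole
  enrichment `E = ⟨I_breadth⟩ / ⟨I_pole⟩`; metaphase cortex/cytosol
  ratio; ingression duration from anaphase onset to membrane closure;
  and n / mean / SD group summaries.
- **Ring-closure symmetry** — end-on reslicing of the Z-stack, direct
  least-squares ellipse fits of manual ring outlines reduced to best-fit
  circles (r = (a+b)/2), first-frame normalization (centre → (0,0),
  radius → 1), the symmetry value
  `s = ‖c_last − c_first‖ / r_first`, and its classification
  (s < 0.2 symmetric, 0.2 ≤ s ≤ 0.6 asymmetric, s > 0.6 highly
  asymmetric).
- **A synthetic dividing-cell simulator** — a calibrated spherical-shell
  phantom with a Gaussian equatorial band of controllable breadth and
  fold-enrichment, symmetric or one-sided furrow ingression,
  photobleaching, background and shot noise — whose ground truth makes
  every stage testable without microscope data.

## Worked example

`examples/linescan_breadth.py` simulates one dividing cell (8-fold,
2 µm-σ equatorial band on a 10 µm cell, 5 % Gaussian noise),
preprocesses the movie and measures the furrow-onset linescan:

```
samples along cortex:   153
baseline (polar) level: 199.3 a.u.
peak height:            1351.6 a.u.
breadth @50% cutoff:    4.60 um (generative truth 4.71 um)
breadth @75% cutoff:    3.00 um
furrow/pole enrichment: 7.15-fold (generative fold 8.0)
```

The 50 %-cutoff breadth recovers the analytic band width
2σ√(2 ln 2) ≈ 4.71 µm within a few percent; the enrichment ratio sits
below the generative peak fold because it averages the band over the
breadth region rather than reading the single peak sample (see
`docs/methods.md`). `examples/ring_symmetry.py` scores closing-ring
trajectories and reproduces a 21-cell cohort summary:

```
generative asymmetry 0.0 -> symmetry value 0.022 (symmetric)
generative asymmetry 0.3 -> symmetry value 0.278 (asymmetric)
generative asymmetry 0.8 -> symmetry value 0.778 (highly_asymmetric)

         category  count  percent
        symmetric      1      4.8
       asymmetric     13     61.9
highly_asymmetric      7     33.3
```

`examples/full_pipeline.py` runs the same measurements through the
manifest-driven pipeline (`run_pipeline`), writing provenance-stamped
CSV tables; `examples/simulate_movie.py` writes a phantom movie and its
ground truth to TIFF/JSON. A thin CLI wraps the same stages:

```sh
ringmetrics simulate --out movie.tif --truth truth.json --seed 1
ringmetrics report --manifest manifest.json
```

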