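# linacqa

Analysis toolkit for linac commissioning QA in the TG-119 style:

* **MLC QA** — picket-fence peak detection (sub-pixel), FWHM, tolerance
  comparison with sub-millimetre error flagging; dose-rate/gantry-speed
  (DR_GS) and leaf-speed/dose-rate (LS_DR) strip tests with open-field
  correction (`R_corr = strip / open × 100`) and per-strip deviation
  statistics.
* **Film dosimetry** — optical density conversion, per-channel cubic
  calibration (dose as a polynomial in OD), dose mapping, and rigid
  film-to-plan registration by normalized cross-correlation.
* **Gamma analysis** — 2D gamma index (dose difference + distance to
  agreement) with global-max or local normalization, low-dose threshold,
  and passing-rate evaluation.
* **TG-119 statistics** — point-dose difference ratios, confidence limits
  (`|mean| + 1.96σ` for point doses, `100 − mean + 1.96σ` for gamma
  passing rates), per-energy aggregation, and couch-transmission
  differences.
* **Synthetic data** — seeded generators for FF/FFF beam planes,
  picket-fence images with injectable sub-millimetre leaf offsets, strip
  patterns, 48-bit RGB film calibration scans, and per-case measurement
  tables, each returning its ground truth.

A reference commissioning dataset (per-case measurements for five photon
energies, IMRT and RapidArc) ships in `linacqa.datasets` and anchors the
regression tests.

## CLI

All functionality is exposed through the `linacqa` entry point:

```sh
# synthetic inputs (seed is mandatory)
linacqa synth beam --mode FFF --seed 1 beam.csv
linacqa synth picketfence --offset 2 0.5 --seed 1 pf.csv
linacqa synth strips --seed 1 strip.csv open.csv
linacqa synth film --seed 1 cal.tif
linacqa synth cases --bias 0.01 --sd 0.005 --seed 1 cases.csv

# analyses
linacqa picketfence --count 5 pf.csv pf_ref.csv report.csv
linacqa strips strip.csv open.csv strips_report.csv
linacqa film-calibrate --doses 0.4,...,3.2 --i0 50000 --rois ... cal.tif cal.json
linacqa film-to-dose --i0 50000 scan.tif cal.json dose.csv
linacqa gamma --dose-tol 3 --dta 3 ref.csv eval.csv gamma.csv
linacqa cl --points cases.csv report
```

Planes travel as a plain-text `csv-grid` format (spacing/origin headers +
comma-separated rows; bit-exact round trip) or 16-bit TIFF scans; tables
as CSV.

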