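# Demo pipeline configuration: two synthetic counties, coarse spline.
# Run with:  rangetrends run --config examples/demo_config.yaml --outdir scratch/demo
outdir: scratch/demo
seed: 3
simulate_scenario: true
spline_m: 6
periods:
  - label: baseline
    start_year: 1977
    end_year: 1980
  - label: recent
    start_year: 2011
    end_year: 2013
    county_end_overrides:
      Amaro: 2016
scenario_overrides:
  county_areas:
    Amaro: 9000.0
    Baruk: 23000.0
selection_criterion: aicc
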