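{
  "version": "1.0",
  "comment": "Signal templates for the urinary metabolite panel. Chemical shifts and multiplet splittings are literature-standard values for urine at ~pH 7 on a 600 MHz instrument (J in Hz converted to ppm at 600 MHz). They are project constants: the exact signals quantified in the original study were not published.",
  "templates": [
    {
      "metabolite": "tsp",
      "center": 0.0,
      "components": [{"offset": 0.0, "weight": 1.0}],
      "fwhm": 0.0025,
      "fit_window": [-0.05, 0.05],
      "fwhm_bounds": [0.0008, 0.01],
      "reference": true
    },
    {
      "metabolite": "lactate",
      "center": 1.33,
      "components": [{"offset": -0.00575, "weight": 0.5}, {"offset": 0.00575, "weight": 0.5}],
      "fwhm": 0.0025,
      "fit_window": [1.29, 1.37],
      "fwhm_bounds": [0.0008, 0.01]
    },
    {
      "metabolite": "alanine",
      "center": 1.48,
      "components": [{"offset": -0.006, "weight": 0.5}, {"offset": 0.006, "weight": 0.5}],
      "fwhm": 0.0025,
      "fit_window": [1.44, 1.52],
      "fwhm_bounds": [0.0008, 0.01]
    },
    {
      "metabolite": "citrate",
      "center": 2.596,
      "components": [
        {"offset": -0.069, "weight": 0.25},
        {"offset": -0.043, "weight": 0.25},
        {"offset": 0.043, "weight": 0.25},
        {"offset": 0.069, "weight": 0.25}
      ],
      "fwhm": 0.0025,
      "fit_window": [2.48, 2.70],
      "fwhm_bounds": [0.0008, 0.012]
    },
    {
      "metabolite": "dma",
      "center": 2.72,
      "components": [{"offset": 0.0, "weight": 1.0}],
      "fwhm": 0.0025,
      "fit_window": [2.703, 2.745],
      "fwhm_bounds": [0.0008, 0.01]
    },
    {
      "metabolite": "creatinine",
      "center": 3.05,
      "components": [{"offset": 0.0, "weight": 1.0}],
      "fwhm": 0.0025,
      "fit_window": [3.00, 3.10],
      "fwhm_bounds": [0.0008, 0.012]
    },
    {
      "metabolite": "trigonelline",
      "center": 4.43,
      "components": [{"offset": 0.0, "weight": 1.0}],
      "fwhm": 0.0025,
      "fit_window": [4.39, 4.47],
      "fwhm_bounds": [0.0008, 0.01]
    },
    {
      "metabolite": "glucose",
      "center": 5.233,
      "components": [{"offset": -0.00315, "weight": 0.5}, {"offset": 0.00315, "weight": 0.5}],
      "fwhm": 0.0025,
      "fit_window": [5.19, 5.33],
      "fwhm_bounds": [0.0008, 0.01],
      "joint_group": "glucose_glucuronate"
    },
    {
      "metabolite": "glucuronate",
      "center": 5.275,
      "components": [{"offset": -0.00325, "weight": 0.5}, {"offset": 0.00325, "weight": 0.5}],
      "fwhm": 0.0025,
      "fit_window": [5.19, 5.33],
      "fwhm_bounds": [0.0008, 0.01],
      "joint_group": "glucose_glucuronate"
    },
    {
      "metabolite": "urea",
      "center": 5.78,
      "components": [{"offset": 0.0, "weight": 1.0}],
      "fwhm": 0.012,
      "fit_window": [5.68, 5.88],
      "fwhm_bounds": [0.004, 0.05]
    },
    {
      "metabolite": "paq",
      "center": 7.42,
      "components": [{"offset": -0.006, "weight": 0.5}, {"offset": 0.006, "weight": 0.5}],
      "fwhm": 0.0025,
      "fit_window": [7.38, 7.46],
      "fwhm_bounds": [0.0008, 0.01]
    },
    {
      "metabolite": "hippurate",
      "center": 7.83,
      "components": [{"offset": -0.0065, "weight": 0.5}, {"offset": 0.0065, "weight": 0.5}],
      "fwhm": 0.0025,
      "fit_window": [7.79, 7.87],
      "fwhm_bounds": [0.0008, 0.01]
    }
  ]
}
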