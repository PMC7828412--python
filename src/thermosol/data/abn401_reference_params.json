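{
  "comment": "Literature-reported solubility-model parameters for the c-Met inhibitor ABN401 in eleven pure solvents and in Transcutol HP-water binary mixtures, 298.15-318.15 K. Scale factors from the published tables are already applied: lam and h are stored as the true parameter values. Yalkowsky endpoint ln x values are the published pure-solvent columns.",
  "drug": {
    "name": "ABN401",
    "molar_mass_g_mol": 566.66,
    "Tfus_K": 413.09,
    "dHfus_J_mol": 20320.0
  },
  "temperatures_K": [298.15, 303.15, 308.15, 313.15, 318.15],
  "pure_solvents": {
    "water": {
      "apelblat": {"A": -374.54, "B": 14006.70, "C": 55.25},
      "vanthoff": {"a": -2.72, "b": -2997.05},
      "bkm": {"lam": 3.0e-5, "h": 8.15e7}
    },
    "methanol": {
      "apelblat": {"A": 490.45, "B": -26827.80, "C": -72.07},
      "vanthoff": {"a": 5.46, "b": -4646.29},
      "bkm": {"lam": 2.94e-3, "h": 1552960.0}
    },
    "ethanol": {
      "apelblat": {"A": 787.98, "B": -41435.30, "C": -115.39},
      "vanthoff": {"a": 11.44, "b": -5922.71},
      "bkm": {"lam": 5.973e-2, "h": 99600.0}
    },
    "1-propanol": {
      "apelblat": {"A": 273.94, "B": -14746.60, "C": -40.67},
      "vanthoff": {"a": 0.25, "b": -2229.99},
      "bkm": {"lam": 2.98e-3, "h": 581150.0}
    },
    "2-propanol": {
      "apelblat": {"A": 205.50, "B": -13595.70, "C": -29.52},
      "vanthoff": {"a": 6.88, "b": -4512.17},
      "bkm": {"lam": 1.643e-2, "h": 268800.0}
    },
    "1-butanol": {
      "apelblat": {"A": -65.44, "B": 1399.93, "C": 9.42},
      "vanthoff": {"a": -2.07, "b": -1497.91},
      "bkm": {"lam": 6.1e-4, "h": 954680.0}
    },
    "2-butanol": {
      "apelblat": {"A": 841.86, "B": -43078.50, "C": -123.77},
      "vanthoff": {"a": 8.97, "b": -4988.55},
      "bkm": {"lam": 4.456e-2, "h": 110990.0}
    },
    "acetonitrile": {
      "apelblat": {"A": 120.15, "B": -7033.34, "C": -18.25},
      "vanthoff": {"a": -2.66, "b": -1417.25},
      "bkm": {"lam": 4.0e-4, "h": 1349000.0}
    },
    "acetone": {
      "apelblat": {"A": -318.55, "B": 12641.10, "C": 47.25},
      "vanthoff": {"a": -0.58, "b": -1900.52},
      "bkm": {"lam": 2.25e-3, "h": 570210.0}
    },
    "ethyl acetate": {
      "apelblat": {"A": -31.99, "B": 264.30, "C": 4.17},
      "vanthoff": {"a": -3.93, "b": -1018.83},
      "bkm": {"lam": 1.9e-4, "h": 1936120.0}
    },
    "transcutol HP": {
      "apelblat": {"A": 456.50, "B": -23707.90, "C": -67.25},
      "vanthoff": {"a": 3.92, "b": -3010.37},
      "bkm": {"lam": 2.587e-2, "h": 106470.0}
    }
  },
  "binary_mixture": {
    "solvent1": "water",
    "solvent2": "transcutol HP",
    "rows": [
      {"w2": 0.0, "apelblat": {"A": -374.974, "B": 14025.4, "C": 55.2935}, "vanthoff": {"a": -2.84474, "b": -2999.98}, "bkm": {"lam": 1.8e-5, "h": 117563000.0}},
      {"w2": 0.1, "apelblat": {"A": -210.273, "B": 7229.53, "C": 30.6005}, "vanthoff": {"a": -4.32968, "b": -2192.64}, "bkm": {"lam": 2.1e-5, "h": 55381800.0}},
      {"w2": 0.2, "apelblat": {"A": 1291.7, "B": -62115.9, "C": -192.138}, "vanthoff": {"a": -1.40214, "b": -2954.84}, "bkm": {"lam": 1.35e-4, "h": 17284600.0}},
      {"w2": 0.3, "apelblat": {"A": 845.029, "B": -42649.8, "C": -125.119}, "vanthoff": {"a": 2.97107, "b": -4124.51}, "bkm": {"lam": 7.02e-4, "h": 4819560.0}},
      {"w2": 0.4, "apelblat": {"A": -3387.62, "B": 150906.0, "C": 503.981}, "vanthoff": {"a": 4.20757, "b": -4273.88}, "bkm": {"lam": 2.208e-3, "h": 1672140.0}},
      {"w2": 0.5, "apelblat": {"A": 1816.02, "B": -86808.6, "C": -269.254}, "vanthoff": {"a": 3.92576, "b": -3902.93}, "bkm": {"lam": 4.872e-3, "h": 693367.0}},
      {"w2": 0.6, "apelblat": {"A": 339.704, "B": -17966.0, "C": -50.5433}, "vanthoff": {"a": -0.456256, "b": -2403.26}, "bkm": {"lam": 1.494e-3, "h": 1003250.0}},
      {"w2": 0.7, "apelblat": {"A": 57.707, "B": -4651.25, "C": -8.79499}, "vanthoff": {"a": -1.483921, "b": -1943.19}, "bkm": {"lam": 1.193e-3, "h": 706422.0}},
      {"w2": 0.8, "apelblat": {"A": -615.06, "B": 25244.2, "C": 91.7279}, "vanthoff": {"a": -2.27488, "b": -3019.63}, "bkm": {"lam": 9.504e-3, "h": 223656.0}},
      {"w2": 0.9, "apelblat": {"A": -1264.99, "B": 55224.9, "C": 188.166}, "vanthoff": {"a": 1.38631, "b": -2713.24}, "bkm": {"lam": 1.0772e-2, "h": 169065.0}},
      {"w2": 1.0, "apelblat": {"A": 456.071, "B": -23804.5, "C": -67.4966}, "vanthoff": {"a": 1.81408, "b": -3021.68}, "bkm": {"lam": 1.5432e-2, "h": 145412.0}}
    ],
    "javh": {
      "alpha1": -0.97, "alpha2": -3128.83, "alpha3": 4.12, "alpha4": -2907.49,
      "J0": 86.86, "J1": -1664.92, "J2": -1593.51
    },
    "yalkowsky_endpoints": {
      "temperatures_K": [298.15, 303.15, 308.15, 313.15, 318.15],
      "lnx_solvent1": [-12.78, -12.61, -12.46, -12.34, -12.12],
      "lnx_solvent2": [-6.19, -6.03, -5.83, -5.66, -5.58]
    }
  }
}
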