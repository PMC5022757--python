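{
  "description": "Three-case soft-tissue sarcoma reference cohort (extremity tumors): per-region anisotropy vectors on the imaging axes, the reported integer isotropy-error percentages, and the Euler angles of each case's applied-field frame. 'error_formula_consistent' flags, per axis, whether the reported integer equals the truncated value of 100*|A_i - 1/sqrt(3)|/(1/sqrt(3)); inconsistent cells appear scrambled in the original report and are excluded from numeric checks.",
  "axis_semantics": "x:L-R y:A-P z:H-F",
  "cases": [
    {
      "case": "case1",
      "site": "forearm",
      "angles_deg_ccw": {"alpha": -4, "theta": 36, "phi": -26},
      "tissues": {
        "soft_tissue": {
          "A": [0.642, 0.569, 0.513],
          "reported_error_pct": [11, 11, 1],
          "error_formula_consistent": [true, false, false]
        },
        "tumor": {
          "A": [0.690, 0.475, 0.564],
          "reported_error_pct": [19, 17, 5],
          "error_formula_consistent": [true, true, false]
        },
        "bone": {
          "A": [0.527, 0.507, 0.682],
          "reported_error_pct": [18, 12, 18],
          "error_formula_consistent": [false, true, true]
        }
      }
    },
    {
      "case": "case2",
      "site": "leg",
      "angles_deg_ccw": {"alpha": -12, "theta": 10, "phi": 46},
      "tissues": {
        "soft_tissue": {
          "A": [0.511, 0.498, 0.70],
          "reported_error_pct": [11, 13, 21],
          "error_formula_consistent": [true, true, true]
        },
        "tumor": {
          "A": [0.670, 0.521, 0.529],
          "reported_error_pct": [16, 9, 8],
          "error_formula_consistent": [true, true, true]
        },
        "bone": {
          "A": [0.492, 0.598, 0.632],
          "reported_error_pct": [14, 3, 10],
          "error_formula_consistent": [true, true, false]
        }
      }
    },
    {
      "case": "case3",
      "site": "thigh",
      "angles_deg_ccw": {"alpha": 31, "theta": -18, "phi": -22},
      "tissues": {
        "soft_tissue": {
          "A": [0.615, 0.568, 0.547],
          "reported_error_pct": [7, 5, 2],
          "error_formula_consistent": [false, false, false]
        },
        "tumor": {
          "A": [0.631, 0.478, 0.611],
          "reported_error_pct": [9, 6, 17],
          "error_formula_consistent": [true, false, false]
        },
        "bone": {
          "A": [0.651, 0.499, 0.572],
          "reported_error_pct": [13, 14, 1],
          "error_formula_consistent": [false, false, false]
        }
      }
    }
  ]
}
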