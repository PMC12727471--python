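{
  "format": "lfnmr-metabolite-library-v1",
  "comment": "Spin-system parameters (chemical shifts in ppm, scalar couplings in Hz) for the bundled metabolite set. Values are GISSMO/BMRB- and HMDB-derived literature values for aqueous solutions near pH 7; third-decimal ppm accuracy is not guaranteed and downstream bound reproductions are correspondingly approximate. Glucose is split into its alpha and beta pyranose anomers with equilibrium populations 0.36/0.64 under the shared parent name 'glucose'. Citrate is the classic strongly coupled AB pair of each of its two equivalent CH2 groups. TSP is the 0.00-ppm chemical-shift reference: nine equivalent, uncoupled trimethylsilyl protons.",
  "systems": [
    {
      "name": "glucose_alpha",
      "parent": "glucose",
      "source_id": "GISSMO bmse000015 / HMDB0000122 (alpha-D-glucopyranose)",
      "population": 0.36,
      "spins": [
        {"label": "H1", "shift_ppm": 5.216},
        {"label": "H2", "shift_ppm": 3.519},
        {"label": "H3", "shift_ppm": 3.698},
        {"label": "H4", "shift_ppm": 3.395},
        {"label": "H5", "shift_ppm": 3.822},
        {"label": "H6a", "shift_ppm": 3.826},
        {"label": "H6b", "shift_ppm": 3.749}
      ],
      "couplings": [
        [0.0, 3.8, 0.0, 0.0, 0.0, 0.0, 0.0],
        [3.8, 0.0, 9.7, 0.0, 0.0, 0.0, 0.0],
        [0.0, 9.7, 0.0, 9.3, 0.0, 0.0, 0.0],
        [0.0, 0.0, 9.3, 0.0, 10.0, 0.0, 0.0],
        [0.0, 0.0, 0.0, 10.0, 0.0, 2.3, 5.3],
        [0.0, 0.0, 0.0, 0.0, 2.3, 0.0, -12.3],
        [0.0, 0.0, 0.0, 0.0, 5.3, -12.3, 0.0]
      ]
    },
    {
      "name": "glucose_beta",
      "parent": "glucose",
      "source_id": "GISSMO bmse000015 / HMDB0000122 (beta-D-glucopyranose)",
      "population": 0.64,
      "spins": [
        {"label": "H1", "shift_ppm": 4.634},
        {"label": "H2", "shift_ppm": 3.232},
        {"label": "H3", "shift_ppm": 3.473},
        {"label": "H4", "shift_ppm": 3.387},
        {"label": "H5", "shift_ppm": 3.450},
        {"label": "H6a", "shift_ppm": 3.882},
        {"label": "H6b", "shift_ppm": 3.707}
      ],
      "couplings": [
        [0.0, 7.9, 0.0, 0.0, 0.0, 0.0, 0.0],
        [7.9, 0.0, 9.4, 0.0, 0.0, 0.0, 0.0],
        [0.0, 9.4, 0.0, 9.1, 0.0, 0.0, 0.0],
        [0.0, 0.0, 9.1, 0.0, 9.9, 0.0, 0.0],
        [0.0, 0.0, 0.0, 9.9, 0.0, 2.2, 5.9],
        [0.0, 0.0, 0.0, 0.0, 2.2, 0.0, -12.3],
        [0.0, 0.0, 0.0, 0.0, 5.9, -12.3, 0.0]
      ]
    },
    {
      "name": "lactate",
      "source_id": "GISSMO bmse000208 / HMDB0000190 (L-lactate)",
      "population": 1.0,
      "spins": [
        {"label": "H2", "shift_ppm": 4.11},
        {"label": "CH3", "shift_ppm": 1.33},
        {"label": "CH3", "shift_ppm": 1.33},
        {"label": "CH3", "shift_ppm": 1.33}
      ],
      "equivalence_groups": [[1, 2, 3]],
      "couplings": [
        [0.0, 6.95, 6.95, 6.95],
        [6.95, 0.0, 0.0, 0.0],
        [6.95, 0.0, 0.0, 0.0],
        [6.95, 0.0, 0.0, 0.0]
      ]
    },
    {
      "name": "citrate",
      "source_id": "GISSMO bmse000458 / HMDB0000094 (citrate)",
      "population": 1.0,
      "spins": [
        {"label": "CH2a-1", "shift_ppm": 2.672},
        {"label": "CH2b-1", "shift_ppm": 2.539},
        {"label": "CH2a-2", "shift_ppm": 2.672},
        {"label": "CH2b-2", "shift_ppm": 2.539}
      ],
      "equivalence_groups": [[0, 2], [1, 3]],
      "couplings": [
        [0.0, -15.4, 0.0, 0.0],
        [-15.4, 0.0, 0.0, 0.0],
        [0.0, 0.0, 0.0, -15.4],
        [0.0, 0.0, -15.4, 0.0]
      ]
    },
    {
      "name": "tsp",
      "source_id": "chemical-shift reference (TSP-d4, nine equivalent Si(CH3)3 protons, 0.00 ppm by definition)",
      "population": 1.0,
      "spins": [
        {"label": "CH3", "shift_ppm": 0.0},
        {"label": "CH3", "shift_ppm": 0.0},
        {"label": "CH3", "shift_ppm": 0.0},
        {"label": "CH3", "shift_ppm": 0.0},
        {"label": "CH3", "shift_ppm": 0.0},
        {"label": "CH3", "shift_ppm": 0.0},
        {"label": "CH3", "shift_ppm": 0.0},
        {"label": "CH3", "shift_ppm": 0.0},
        {"label": "CH3", "shift_ppm": 0.0}
      ],
      "equivalence_groups": [[0, 1, 2, 3, 4, 5, 6, 7, 8]],
      "couplings": [
        [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
        [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
        [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
        [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
        [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
        [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
        [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
        [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
        [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0]
      ]
    }
  ]
}
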