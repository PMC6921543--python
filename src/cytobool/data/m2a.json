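{
  "name": "M2a",
  "stimulus": "IL-4",
  "description": "Published IL-4-induced (alternative) macrophage activation network: 24 cytokines with one input (IL-1alpha), Boolean update rules, LP link weights and attributions, plus the printed 7-node core membership and observed state path. The published core collapse is under-determined, so no collapsed core rules are shipped.",
  "nodes": [
    "FGF-9", "GM-CSF", "IFN-gamma", "IP-10", "IL-1alpha", "IL-2", "IL-3",
    "IL-4", "IL-6", "IL-7", "IL-10", "IL-12p70", "IL-17A", "Lymphotactin",
    "MIP-1beta", "MIP-2", "MCP-1", "MCP-3", "MCP-5", "OSM", "SCF", "TIMP-1",
    "TNF-alpha", "VEGF-A"
  ],
  "inputs": ["IL-1alpha"],
  "rules": {
    "FGF-9": {
      "terms": [
        [["MIP-2", true], ["VEGF-A", true]],
        [["MIP-2", false], ["VEGF-A", false]],
        [["MIP-2", true], ["Lymphotactin", false]]
      ],
      "weights": {"MIP-2": 89.6, "VEGF-A": 87, "Lymphotactin": -82},
      "attribution": "IS"
    },
    "GM-CSF": {
      "terms": [[["MCP-1", true]], [["SCF", false]]],
      "weights": {"MCP-1": 2.75, "SCF": -3.23},
      "attribution": "Output"
    },
    "IFN-gamma": {
      "terms": [[["MIP-2", false]], [["VEGF-A", true]]],
      "weights": {"MIP-2": 34, "VEGF-A": -31.7},
      "attribution": "IS"
    },
    "IP-10": {
      "terms": [[["VEGF-A", false]]],
      "weights": {"VEGF-A": 121},
      "attribution": "IS"
    },
    "IL-2": {
      "terms": [[["MCP-3", false]]],
      "weights": {"MCP-3": 92.7},
      "attribution": "IS"
    },
    "IL-3": {
      "terms": [[["MCP-3", false]]],
      "weights": {"MCP-3": 41.9},
      "attribution": "Output"
    },
    "IL-4": {
      "terms": [[["MCP-1", false]]],
      "weights": {"MCP-1": 151},
      "attribution": "Output"
    },
    "IL-6": {
      "terms": [[["Lymphotactin", false]]],
      "weights": {"Lymphotactin": 58.7},
      "attribution": "Output"
    },
    "IL-7": {
      "terms": [[["IL-1alpha", false], ["MCP-5", false]]],
      "weights": {"IL-1alpha": -0.9, "MCP-5": -1},
      "attribution": "Output"
    },
    "IL-10": {
      "terms": [[["VEGF-A", false]]],
      "weights": {"VEGF-A": -296},
      "attribution": "IS"
    },
    "IL-12p70": {
      "terms": [[["Lymphotactin", false]]],
      "weights": {"Lymphotactin": 0.557},
      "attribution": "Output"
    },
    "IL-17A": {
      "terms": [[["MCP-3", false]]],
      "weights": {"MCP-3": 0.34},
      "attribution": "Output"
    },
    "Lymphotactin": {
      "terms": [[["IL-1alpha", false], ["MCP-5", false]]],
      "weights": {"IL-1alpha": 192, "MCP-5": -159},
      "attribution": "IS"
    },
    "MIP-1beta": {
      "terms": [[["IL-1alpha", false], ["MCP-1", false]]],
      "weights": {"IL-1alpha": -6490, "MCP-1": 6650},
      "attribution": "IS"
    },
    "MIP-2": {
      "terms": [[["MCP-3", false], ["MCP-5", false]]],
      "weights": {"MCP-3": 816, "MCP-5": -1160},
      "attribution": "IS"
    },
    "MCP-1": {
      "terms": [[["IL-2", true], ["MIP-1beta", true]]],
      "weights": {"IL-2": -6150, "MIP-1beta": -6520},
      "attribution": "IS"
    },
    "MCP-3": {
      "terms": [[["IFN-gamma", false], ["MCP-1", false]]],
      "weights": {"IFN-gamma": -15900, "MCP-1": 16800},
      "attribution": "IS"
    },
    "MCP-5": {
      "terms": [[["SCF", false]], [["VEGF-A", true]]],
      "weights": {"SCF": 1300, "VEGF-A": -1140},
      "attribution": "IS"
    },
    "OSM": {
      "terms": [[["MCP-1", false]]],
      "weights": {"MCP-1": 1.11},
      "attribution": "Output"
    },
    "SCF": {
      "terms": [[["FGF-9", false], ["IL-10", false]]],
      "weights": {"FGF-9": 12700, "IL-10": -14400},
      "attribution": "IS"
    },
    "TIMP-1": {
      "terms": [[["Lymphotactin", false]]],
      "weights": {"Lymphotactin": 1.19},
      "attribution": "Output"
    },
    "TNF-alpha": {
      "terms": [[["IL-2", false]]],
      "weights": {"IL-2": -0.188},
      "attribution": "Output"
    },
    "VEGF-A": {
      "terms": [[["MCP-5", false], ["SCF", false]]],
      "weights": {"MCP-5": -13400, "SCF": 13300},
      "attribution": "IS"
    }
  },
  "core": {
    "nodes": ["VEGF-A", "FGF-9", "MIP-1beta", "MCP-5", "SCF", "MIP-2", "MCP-1"],
    "rules": null,
    "collapsed": null
  },
  "trajectory": {
    "node_order": ["VEGF-A", "FGF-9", "MIP-1beta", "MCP-5", "SCF", "MIP-2", "MCP-1"],
    "indices": [3, 4, 20, 84, 120],
    "states": [
      [1, 1, 1, 1, 1, 0, 1],
      [1, 1, 1, 1, 1, 0, 0],
      [1, 1, 0, 1, 1, 0, 0],
      [0, 1, 0, 1, 1, 0, 0],
      [0, 0, 0, 1, 0, 0, 0]
    ]
  },
  "stable_states": {
    "88": [0, 1, 0, 1, 0, 0, 0],
    "1": [1, 1, 1, 1, 1, 1, 1]
  },
  "table2": {
    "full": {"nodes": 27, "density": 12.9, "links": 348, "promotion": 189,
             "inhibition": 159, "inputs": 0, "outputs": 6},
    "simplified": {"nodes": 24, "density": 1.5, "links": 36, "promotion": 19,
                   "inhibition": 17, "inputs": 1, "outputs": 11,
                   "attractors": 0, "ge4_parents": 0}
  },
  "notes": "The MCP-1 rule is printed with garbled overbars; both weights are negative, so it is stored as !IL-2 & !MIP-1beta, the reading consistent with the LP signs. Per-link weight signs sometimes contradict the printed literal polarity (e.g. MIP-1beta on IL-1alpha); weights are stored verbatim."
}
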