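{
  "name": "M1",
  "stimulus": "LPS",
  "description": "Published LPS-induced (classical) macrophage activation network: 26 cytokines (TIMP-1 dropped as an orphan), Boolean update rules, LP link weights and node attributions, plus the 6-node core and its observed state path.",
  "nodes": [
    "FGF-9", "GM-CSF", "KC-GRO", "IFN-gamma", "IP-10", "IL-1alpha", "IL-2",
    "IL-3", "IL-4", "IL-6", "IL-7", "IL-10", "IL-11", "IL-12p70", "IL-17A",
    "Lymphotactin", "MIP-1beta", "MIP-2", "MCP-1", "MCP-3", "MCP-5", "OSM",
    "SCF", "RANTES", "TNF-alpha", "VEGF-A"
  ],
  "inputs": ["FGF-9", "IL-4"],
  "rules": {
    "GM-CSF": {
      "terms": [[["IFN-gamma", true], ["MCP-5", false]]],
      "weights": {"IFN-gamma": -180, "MCP-5": 185},
      "attribution": "Output"
    },
    "KC-GRO": {
      "terms": [[["IL-10", false], ["MCP-5", true]]],
      "weights": {"IL-10": 5.45, "MCP-5": -5.82},
      "attribution": "IS"
    },
    "IFN-gamma": {
      "terms": [[["SCF", false]], [["IFN-gamma", false]]],
      "weights": {"SCF": 1170},
      "attribution": "IS"
    },
    "IP-10": {
      "terms": [[["IL-10", false], ["MCP-5", false]]],
      "weights": {"IL-10": 68100, "MCP-5": 85000},
      "attribution": "Output"
    },
    "IL-1alpha": {
      "terms": [[["Lymphotactin", false]]],
      "weights": {"Lymphotactin": 787000},
      "attribution": "IS"
    },
    "IL-2": {
      "terms": [
        [["KC-GRO", true], ["MIP-2", true]],
        [["KC-GRO", false], ["RANTES", true]]
      ],
      "weights": {"KC-GRO": 34.7, "MIP-2": -27, "RANTES": -33.8},
      "attribution": "Output"
    },
    "IL-3": {
      "terms": [[["SCF", false]]],
      "weights": {"SCF": 302},
      "attribution": "IS"
    },
    "IL-6": {
      "terms": [[["IL-1alpha", false], ["RANTES", true]]],
      "weights": {"IL-1alpha": 3840, "RANTES": -4840},
      "attribution": "Output"
    },
    "IL-7": {
      "terms": [[["MIP-1beta", false]]],
      "weights": {"MIP-1beta": 10},
      "attribution": "Output"
    },
    "IL-10": {
      "terms": [[["IL-4", true], ["Lymphotactin", false]]],
      "weights": {"IL-4": -64700, "Lymphotactin": 48600},
      "attribution": "IS"
    },
    "IL-11": {
      "terms": [[["FGF-9", false]]],
      "weights": {"FGF-9": 6190},
      "attribution": "IS"
    },
    "IL-12p70": {
      "terms": [[["MCP-5", false]]],
      "weights": {"MCP-5": 5.6},
      "attribution": "Output"
    },
    "IL-17A": {
      "terms": [[["MCP-5", false]]],
      "weights": {"MCP-5": 0.555},
      "attribution": "Output"
    },
    "Lymphotactin": {
      "terms": [[["IFN-gamma", true]]],
      "weights": {"IFN-gamma": -1675},
      "attribution": "IS"
    },
    "MIP-1beta": {
      "terms": [[["IL-3", false]], [["IL-11", false]]],
      "weights": {"IL-3": 44800, "IL-11": 41600},
      "attribution": "IS"
    },
    "MIP-2": {
      "terms": [[["IL-10", false], ["MIP-1beta", true]]],
      "weights": {"IL-10": 7880, "MIP-1beta": -10400},
      "attribution": "IS"
    },
    "MCP-1": {
      "terms": [[["IFN-gamma", true]]],
      "weights": {"IFN-gamma": -5090},
      "attribution": "IS"
    },
    "MCP-3": {
      "terms": [
        [["IL-4", false], ["FGF-9", false]],
        [["FGF-9", true], ["RANTES", true]]
      ],
      "weights": {"IL-4": 27600, "FGF-9": 22800, "RANTES": -27400},
      "attribution": "IS"
    },
    "MCP-5": {
      "terms": [[["Lymphotactin", false], ["MCP-1", false]]],
      "weights": {"Lymphotactin": 5840, "MCP-1": -4590},
      "attribution": "IS"
    },
    "OSM": {
      "terms": [[["IL-10", false], ["MIP-1beta", false]]],
      "weights": {"IL-10": 6.45, "MIP-1beta": 6.19},
      "attribution": "Output"
    },
    "SCF": {
      "terms": [[["IL-1alpha", true]]],
      "weights": {"IL-1alpha": -70800},
      "attribution": "IS"
    },
    "RANTES": {
      "terms": [[["MCP-3", true]]],
      "weights": {"MCP-3": 304},
      "attribution": "IS"
    },
    "TNF-alpha": {
      "terms": [[["IL-1alpha", true]]],
      "weights": {"IL-1alpha": -1.37},
      "attribution": "Output"
    },
    "VEGF-A": {
      "terms": [[["MCP-5", true]]],
      "weights": {"MCP-5": -17850},
      "attribution": "Output"
    }
  },
  "core": {
    "nodes": ["MCP-5", "Lymphotactin", "IL-1alpha", "SCF", "IFN-gamma", "MCP-1"],
    "rules": {
      "MCP-5": [[["Lymphotactin", false], ["MCP-1", false]]],
      "Lymphotactin": [[["IFN-gamma", true]]],
      "IL-1alpha": [[["Lymphotactin", false]]],
      "SCF": [[["IL-1alpha", true]]],
      "IFN-gamma": [[["SCF", false]], [["IFN-gamma", false]]],
      "MCP-1": [[["IFN-gamma", true]]]
    },
    "collapsed": {}
  },
  "trajectory": {
    "node_order": ["MCP-5", "Lymphotactin", "IL-1alpha", "SCF", "IFN-gamma", "MCP-1"],
    "indices": [11, 1, 22, 62, 58],
    "states": [
      [1, 1, 0, 1, 0, 1],
      [1, 1, 1, 1, 1, 1],
      [1, 0, 1, 0, 1, 0],
      [0, 0, 0, 0, 1, 0],
      [0, 0, 0, 1, 1, 0]
    ]
  },
  "stable_states": {
    "58": [0, 0, 0, 1, 1, 0],
    "7": [1, 1, 1, 0, 0, 1]
  },
  "table2": {
    "full": {"nodes": 27, "density": 12.9, "links": 348, "promotion": 189,
             "inhibition": 159, "inputs": 0, "outputs": 5},
    "simplified": {"nodes": 26, "density": 1.5, "links": 39, "promotion": 25,
                   "inhibition": 14, "inputs": 2, "outputs": 10,
                   "attractors": 1, "ge4_parents": 0}
  },
  "notes": "The printed function table enumerates 38 links while the printed summary table reports 39; the discrepancy is shipped as-is and no M1 link count is asserted. The MCP-5 rule carries a negative LP weight on MCP-1 although the printed literal is unnegated; weights are stored verbatim."
}
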