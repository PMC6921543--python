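{
  "name": "M2c",
  "stimulus": "IL-10",
  "description": "Published IL-10-induced (deactivating) macrophage activation network: 24 cytokines (TIMP-1 dropped as an orphan), Boolean update rules, LP link weights and attributions, plus the 5-node core obtained by collapsing the MCP-3 transduction node and the observed state path.",
  "nodes": [
    "FGF-9", "GM-CSF", "IFN-gamma", "IP-10", "IL-1alpha", "IL-2", "IL-3",
    "IL-4", "IL-6", "IL-7", "IL-10", "IL-11", "IL-12p70", "IL-17A",
    "Lymphotactin", "MIP-1beta", "MIP-2", "MCP-1", "MCP-3", "MCP-5", "OSM",
    "SCF", "TNF-alpha", "VEGF-A"
  ],
  "inputs": [],
  "rules": {
    "FGF-9": {
      "terms": [[["MIP-1beta", false]]],
      "weights": {"MIP-1beta": 13},
      "attribution": "IS"
    },
    "GM-CSF": {
      "terms": [[["IP-10", true], ["IL-2", true], ["IL-4", false], ["IL-10", false]]],
      "weights": {"IP-10": -0.83, "IL-2": -0.73, "IL-4": 0.73, "IL-10": 0.75},
      "attribution": "Output"
    },
    "IFN-gamma": {
      "terms": [[["IL-1alpha", false], ["SCF", false]]],
      "weights": {"IL-1alpha": -18, "SCF": 20},
      "attribution": "IS"
    },
    "IP-10": {
      "terms": [[["MCP-1", false], ["MCP-3", false]]],
      "weights": {"MCP-1": -4470, "MCP-3": 4050},
      "attribution": "IS"
    },
    "IL-1alpha": {
      "terms": [[["IL-11", false], ["MCP-3", false]]],
      "weights": {"IL-11": -699, "MCP-3": 609},
      "attribution": "IS"
    },
    "IL-2": {
      "terms": [[["IL-10", false], ["IL-11", true]]],
      "weights": {"IL-10": 5.62, "IL-11": -6.42},
      "attribution": "IS"
    },
    "IL-3": {
      "terms": [[["FGF-9", false], ["IL-1alpha", true], ["MCP-1", true], ["MCP-3", false]]],
      "weights": {"FGF-9": 7.16, "IL-1alpha": -7.99, "MCP-1": -8.86, "MCP-3": 8.68},
      "attribution": "Output"
    },
    "IL-4": {
      "terms": [[["IL-10", false]]],
      "weights": {"IL-10": 41.6},
      "attribution": "IS"
    },
    "IL-6": {
      "terms": [[["IL-1alpha", false], ["MIP-1beta", false], ["MIP-2", true], ["VEGF-A", true]]],
      "weights": {"IL-1alpha": 2.26, "MIP-1beta": 2.09, "MIP-2": -2.4, "VEGF-A": -2.04},
      "attribution": "Output"
    },
    "IL-7": {
      "terms": [[["MCP-3", false]]],
      "weights": {"MCP-3": 0.476},
      "attribution": "Output"
    },
    "IL-10": {
      "terms": [[["MCP-3", false]]],
      "weights": {"MCP-3": 3330},
      "attribution": "IS"
    },
    "IL-11": {
      "terms": [[["IL-1alpha", false]]],
      "weights": {"IL-1alpha": -78.1},
      "attribution": "IS"
    },
    "IL-12p70": {
      "terms": [[["MCP-3", false]], [["SCF", true]]],
      "weights": {"MCP-3": 1.34, "SCF": -1.38},
      "attribution": "Output"
    },
    "IL-17A": {
      "terms": [[["MCP-1", true]], [["MCP-3", false]]],
      "weights": {"MCP-1": -0.236, "MCP-3": 0.19},
      "attribution": "Output"
    },
    "Lymphotactin": {
      "terms": [[["SCF", false]]],
      "weights": {"SCF": 39},
      "attribution": "IS"
    },
    "MIP-1beta": {
      "terms": [[["IL-11", false]]],
      "weights": {"IL-11": -16100},
      "attribution": "IS"
    },
    "MIP-2": {
      "terms": [[["SCF", false]]],
      "weights": {"SCF": 2420},
      "attribution": "IS"
    },
    "MCP-1": {
      "terms": [[["MIP-1beta", false], ["SCF", false]]],
      "weights": {"MIP-1beta": 2050, "SCF": 1920},
      "attribution": "IS"
    },
    "MCP-3": {
      "terms": [[["IFN-gamma", false]]],
      "weights": {"IFN-gamma": 1410},
      "attribution": "IS"
    },
    "MCP-5": {
      "terms": [[["SCF", true]]],
      "weights": {"SCF": -728},
      "attribution": "IS"
    },
    "OSM": {
      "terms": [[["MIP-1beta", false]]],
      "weights": {"MIP-1beta": 0.186},
      "attribution": "Output"
    },
    "SCF": {
      "terms": [[["IL-11", false], ["MCP-5", false]]],
      "weights": {"IL-11": 14700, "MCP-5": -18000},
      "attribution": "State"
    },
    "TNF-alpha": {
      "terms": [[["IP-10", false]]],
      "weights": {"IP-10": 0.156},
      "attribution": "Output"
    },
    "VEGF-A": {
      "terms": [[["Lymphotactin", false]], [["MCP-5", true]]],
      "weights": {"Lymphotactin": 19200, "MCP-5": -24100},
      "attribution": "Output"
    }
  },
  "core": {
    "nodes": ["IL-11", "SCF", "MCP-5", "IL-1alpha", "IFN-gamma"],
    "rules": {
      "IL-11": [[["IL-1alpha", false]]],
      "SCF": [[["IL-11", false], ["MCP-5", false]]],
      "MCP-5": [[["SCF", true]]],
      "IL-1alpha": [[["IL-11", false], ["IFN-gamma", false]]],
      "IFN-gamma": [[["IL-1alpha", false], ["SCF", false]]]
    },
    "collapsed": {
      "MCP-3": {"parent": "IFN-gamma", "child": "IL-1alpha", "negated": false, "delay": 1}
    }
  },
  "trajectory": {
    "node_order": ["IL-11", "SCF", "MCP-5", "IL-1alpha", "IFN-gamma"],
    "indices": [1, 5, 13, 10, 4, 24, 32, 28],
    "states": [
      [1, 1, 1, 1, 1],
      [1, 1, 0, 1, 1],
      [1, 0, 0, 1, 1],
      [1, 0, 1, 1, 0],
      [1, 1, 1, 0, 0],
      [0, 1, 0, 0, 0],
      [0, 0, 0, 0, 0],
      [0, 0, 1, 0, 0]
    ]
  },
  "stable_states": {
    "28": [0, 0, 1, 0, 0]
  },
  "table2": {
    "full": {"nodes": 27, "density": 15, "links": 404, "promotion": 211,
             "inhibition": 193, "inputs": 0, "outputs": 5},
    "simplified": {"nodes": 24, "density": 1.75, "links": 42, "promotion": 25,
                   "inhibition": 17, "inputs": 0, "outputs": 9,
                   "attractors": 0, "ge4_parents": 3}
  },
  "notes": "The IL-3 rule is printed with an ambiguous 'MIP-1' literal; the reference column cites MCP-1, so the parent is stored as MCP-1 (the core reduction result is unchanged under either reading). Some weight signs contradict the printed literal polarity (e.g. IFN-gamma's -18 on the unnegated IL-1alpha literal); weights are stored verbatim."
}
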