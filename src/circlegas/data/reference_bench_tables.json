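{
  "description": "Reference inspired-gas summaries measured on a hardware patient simulator connected to a fresh-gas-decoupled anesthesia workstation (three replicate runs per condition). Window entries are [median, q25, q75, min, max] in % (vol% for sevoflurane); tau entries are [median, q25, q75] in minutes. These are bench measurements with an uncharacterized simulator uptake model: they serve the qualitative comparison report, not as numerical simulation targets.",
  "windows": {
    "oxygen_air": {
      "o2": {
        "0.5": {"before": [44.0, 41.75, 45.0, 40.0, 46.0], "during": [31.5, 30.0, 35.25, 28.0, 45.0], "after": [33.0, 31.75, 34.25, 29.0, 37.0]},
        "1.0": {"before": [55.0, 54.0, 56.0, 52.0, 58.0], "during": [39.5, 38.0, 42.5, 37.0, 49.0], "after": [48.0, 43.75, 50.0, 37.0, 52.0]},
        "2.0": {"before": [64.0, 63.0, 64.0, 62.0, 65.0], "during": [50.0, 49.0, 52.0, 47.0, 64.0], "after": [60.0, 57.5, 61.0, 51.0, 63.0]}
      },
      "sevo": {
        "0.5": {"before": [1.9, 1.8, 1.9, 1.8, 2.0], "during": [1.2, 1.1, 1.35, 1.1, 1.8], "after": [1.5, 1.4, 1.6, 1.1, 1.7]},
        "1.0": {"before": [2.9, 2.8, 2.9, 2.7, 3.0], "during": [1.9, 1.9, 2.2, 1.8, 2.7], "after": [2.7, 2.37, 2.8, 1.8, 3.0]},
        "2.0": {"before": [4.1, 4.0, 4.1, 4.0, 4.1], "during": [3.1, 3.1, 3.4, 3.0, 4.1], "after": [3.9, 3.68, 4.0, 3.1, 4.1]}
      }
    },
    "oxygen_n2o": {
      "o2": {
        "0.5": {"before": [26.0, 24.0, 27.0, 22.0, 29.0], "during": [21.0, 20.0, 21.5, 19.0, 22.0], "after": [23.0, 20.0, 24.0, 18.0, 24.0]},
        "1.0": {"before": [39.0, 38.0, 39.0, 38.0, 40.0], "during": [32.0, 31.0, 32.0, 32.0, 36.0], "after": [37.5, 36.0, 39.0, 33.0, 40.0]},
        "2.0": {"before": [50.0, 49.0, 50.0, 49.0, 51.0], "during": [42.0, 41.0, 43.0, 41.0, 49.0], "after": [49.0, 48.0, 49.25, 43.0, 51.0]}
      },
      "sevo": {
        "0.5": {"before": [1.2, 1.2, 1.2, 1.2, 1.3], "during": [0.8, 0.7, 0.9, 0.7, 1.1], "after": [1.0, 0.9, 1.1, 0.7, 1.1]},
        "1.0": {"before": [1.9, 1.7, 1.9, 1.7, 1.9], "during": [1.3, 1.3, 1.4, 1.2, 1.8], "after": [1.7, 1.6, 1.8, 1.3, 1.9]},
        "2.0": {"before": [2.6, 2.6, 2.7, 2.6, 2.7], "during": [2.2, 2.1, 2.3, 2.1, 2.6], "after": [2.6, 2.47, 2.6, 2.1, 2.8]}
      },
      "n2o": {
        "0.5": {"before": [71.0, 69.0, 72.25, 67.0, 75.0], "during": [38.0, 36.0, 43.25, 35.0, 65.0], "after": [65.5, 55.75, 72.0, 37.0, 76.0]},
        "1.0": {"before": [57.0, 57.0, 58.0, 57.0, 59.0], "during": [33.5, 33.0, 36.25, 32.0, 47.0], "after": [53.0, 48.0, 55.0, 38.0, 57.0]},
        "2.0": {"before": [46.0, 46.0, 46.0, 45.0, 47.0], "during": [33.0, 32.0, 34.0, 32.0, 45.0], "after": [45.0, 43.0, 45.0, 35.0, 46.0]}
      }
    }
  },
  "tau": {
    "oxygen_air": {
      "o2": {"0.5": [2.5, 2.5, 2.5], "1.0": [2.5, 2.5, 2.8], "2.0": [1.5, 1.5, 1.5]},
      "sevo": {"0.5": [2.0, 1.8, 2.25], "1.0": [2.0, 1.8, 2.0], "2.0": [1.5, 1.5, 1.8]}
    },
    "oxygen_n2o": {
      "o2": {"0.5": [1.0, 1.0, 1.0], "1.0": [1.0, 1.0, 1.3], "2.0": [1.0, 1.0, 1.0]},
      "sevo": {"0.5": [3.0, 2.3, 3.0], "1.0": [2.0, 1.8, 2.0], "2.0": [1.0, 1.0, 1.5]},
      "n2o": {"0.5": [1.5, 1.5, 1.8], "1.0": [1.5, 1.3, 1.5], "2.0": [1.0, 1.0, 1.0]}
    }
  }
}
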