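{
 "comment": "RNA duplex nearest-neighbor parameters (Turner/Mathews 1999 set, 37C), kcal/mol",
 "pairs": [
  "CG",
  "GC",
  "GU",
  "UG",
  "AU",
  "UA"
 ],
 "stack": {
  "CG": {
   "CG": -3.3,
   "GC": -2.4,
   "GU": -1.4,
   "UG": -2.1,
   "AU": -2.1,
   "UA": -2.1
  },
  "GC": {
   "CG": -3.4,
   "GC": -3.3,
   "GU": -1.5,
   "UG": -2.5,
   "AU": -2.4,
   "UA": -2.2
  },
  "GU": {
   "CG": -2.5,
   "GC": -2.1,
   "GU": -0.5,
   "UG": 1.3,
   "AU": -1.3,
   "UA": -1.4
  },
  "UG": {
   "CG": -1.5,
   "GC": -1.4,
   "GU": 0.3,
   "UG": -0.5,
   "AU": -1.0,
   "UA": -0.6
  },
  "AU": {
   "CG": -2.2,
   "GC": -2.1,
   "GU": -0.6,
   "UG": -1.4,
   "AU": -0.9,
   "UA": -1.1
  },
  "UA": {
   "CG": -2.4,
   "GC": -2.1,
   "GU": -1.0,
   "UG": -1.3,
   "AU": -1.3,
   "UA": -0.9
  }
 },
 "bulge": [
  null,
  3.8,
  2.8,
  3.2,
  3.6,
  4.0,
  4.4,
  4.59,
  4.7,
  4.8,
  4.9,
  5.0,
  5.1,
  5.19,
  5.27,
  5.34,
  5.41,
  5.48,
  5.54,
  5.6,
  5.65,
  5.71,
  5.76,
  5.8,
  5.85,
  5.89,
  5.94,
  5.98,
  6.02,
  6.05,
  6.09
 ],
 "internal": [
  null,
  null,
  4.1,
  5.1,
  1.7,
  1.8,
  2.0,
  2.2,
  2.3,
  2.4,
  2.5,
  2.6,
  2.7,
  2.78,
  2.86,
  2.94,
  3.01,
  3.07,
  3.13,
  3.19,
  3.25,
  3.3,
  3.35,
  3.4,
  3.45,
  3.49,
  3.53,
  3.57,
  3.61,
  3.65,
  3.69
 ],
 "ninio_m": 0.5,
 "ninio_max": 3.0,
 "terminal_au": 0.5,
 "duplex_init": 4.1,
 "lxc": 1.07856
}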