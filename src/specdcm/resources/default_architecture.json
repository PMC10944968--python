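{
 "b_mask": [
  [
   "EVC_contra",
   "IPS_contra",
   "feedforward"
  ],
  [
   "EVC_contra",
   "MFG_contra",
   "feedforward"
  ],
  [
   "EVC_contra",
   "SFG",
   "feedforward"
  ],
  [
   "EVC_ipsi",
   "IPS_ipsi",
   "feedforward"
  ],
  [
   "EVC_ipsi",
   "MFG_ipsi",
   "feedforward"
  ],
  [
   "EVC_ipsi",
   "SFG",
   "feedforward"
  ],
  [
   "IPS_contra",
   "MFG_contra",
   "feedforward"
  ],
  [
   "IPS_contra",
   "SFG",
   "feedforward"
  ],
  [
   "IPS_ipsi",
   "MFG_ipsi",
   "feedforward"
  ],
  [
   "IPS_ipsi",
   "SFG",
   "feedforward"
  ],
  [
   "SFG",
   "MFG_contra",
   "feedforward"
  ],
  [
   "SFG",
   "MFG_ipsi",
   "feedforward"
  ],
  [
   "IPS_contra",
   "EVC_contra",
   "feedback"
  ],
  [
   "MFG_contra",
   "EVC_contra",
   "feedback"
  ],
  [
   "SFG",
   "EVC_contra",
   "feedback"
  ],
  [
   "IPS_ipsi",
   "EVC_ipsi",
   "feedback"
  ],
  [
   "MFG_ipsi",
   "EVC_ipsi",
   "feedback"
  ],
  [
   "SFG",
   "EVC_ipsi",
   "feedback"
  ],
  [
   "MFG_contra",
   "IPS_contra",
   "feedback"
  ],
  [
   "SFG",
   "IPS_contra",
   "feedback"
  ],
  [
   "MFG_ipsi",
   "IPS_ipsi",
   "feedback"
  ],
  [
   "SFG",
   "IPS_ipsi",
   "feedback"
  ],
  [
   "MFG_contra",
   "SFG",
   "feedback"
  ],
  [
   "MFG_ipsi",
   "SFG",
   "feedback"
  ],
  [
   "EVC_contra",
   "EVC_ipsi",
   "lateral"
  ],
  [
   "EVC_ipsi",
   "EVC_contra",
   "lateral"
  ],
  [
   "IPS_contra",
   "IPS_ipsi",
   "lateral"
  ],
  [
   "IPS_ipsi",
   "IPS_contra",
   "lateral"
  ],
  [
   "MFG_contra",
   "MFG_ipsi",
   "lateral"
  ],
  [
   "MFG_ipsi",
   "MFG_contra",
   "lateral"
  ]
 ],
 "edges": [
  [
   "EVC_contra",
   "IPS_contra",
   "feedforward"
  ],
  [
   "EVC_contra",
   "MFG_contra",
   "feedforward"
  ],
  [
   "EVC_contra",
   "SFG",
   "feedforward"
  ],
  [
   "EVC_ipsi",
   "IPS_ipsi",
   "feedforward"
  ],
  [
   "EVC_ipsi",
   "MFG_ipsi",
   "feedforward"
  ],
  [
   "EVC_ipsi",
   "SFG",
   "feedforward"
  ],
  [
   "IPS_contra",
   "MFG_contra",
   "feedforward"
  ],
  [
   "IPS_contra",
   "SFG",
   "feedforward"
  ],
  [
   "IPS_ipsi",
   "MFG_ipsi",
   "feedforward"
  ],
  [
   "IPS_ipsi",
   "SFG",
   "feedforward"
  ],
  [
   "SFG",
   "MFG_contra",
   "feedforward"
  ],
  [
   "SFG",
   "MFG_ipsi",
   "feedforward"
  ],
  [
   "IPS_contra",
   "EVC_contra",
   "feedback"
  ],
  [
   "MFG_contra",
   "EVC_contra",
   "feedback"
  ],
  [
   "SFG",
   "EVC_contra",
   "feedback"
  ],
  [
   "IPS_ipsi",
   "EVC_ipsi",
   "feedback"
  ],
  [
   "MFG_ipsi",
   "EVC_ipsi",
   "feedback"
  ],
  [
   "SFG",
   "EVC_ipsi",
   "feedback"
  ],
  [
   "MFG_contra",
   "IPS_contra",
   "feedback"
  ],
  [
   "SFG",
   "IPS_contra",
   "feedback"
  ],
  [
   "MFG_ipsi",
   "IPS_ipsi",
   "feedback"
  ],
  [
   "SFG",
   "IPS_ipsi",
   "feedback"
  ],
  [
   "MFG_contra",
   "SFG",
   "feedback"
  ],
  [
   "MFG_ipsi",
   "SFG",
   "feedback"
  ],
  [
   "EVC_contra",
   "EVC_ipsi",
   "lateral"
  ],
  [
   "EVC_ipsi",
   "EVC_contra",
   "lateral"
  ],
  [
   "IPS_contra",
   "IPS_ipsi",
   "lateral"
  ],
  [
   "IPS_ipsi",
   "IPS_contra",
   "lateral"
  ],
  [
   "MFG_contra",
   "MFG_ipsi",
   "lateral"
  ],
  [
   "MFG_ipsi",
   "MFG_contra",
   "lateral"
  ]
 ],
 "hierarchy": {
  "EVC_contra": 1,
  "EVC_ipsi": 1,
  "IPS_contra": 2,
  "IPS_ipsi": 2,
  "MFG_contra": 4,
  "MFG_ipsi": 4,
  "SFG": 3
 },
 "nodes": [
  "EVC_contra",
  "EVC_ipsi",
  "IPS_contra",
  "IPS_ipsi",
  "MFG_contra",
  "MFG_ipsi",
  "SFG"
 ]
}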