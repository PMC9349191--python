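{
 "topology": {
  "name": "toy_branching",
  "column_order": [
   "A",
   "B"
  ],
  "compartments": [
   {
    "id": "S",
    "label": "stem (tip)",
    "level": 0,
    "column": "A",
    "observed": true,
    "is_tip": true,
    "allows_proliferation": true,
    "allows_loss": false
   },
   {
    "id": "A1",
    "label": "progenitor A",
    "level": 1,
    "column": "A",
    "observed": true,
    "is_tip": false,
    "allows_proliferation": true,
    "allows_loss": false
   },
   {
    "id": "B1",
    "label": "progenitor B",
    "level": 1,
    "column": "B",
    "observed": true,
    "is_tip": false,
    "allows_proliferation": true,
    "allows_loss": true
   },
   {
    "id": "A2",
    "label": "mature A",
    "level": 2,
    "column": "A",
    "observed": true,
    "is_tip": false,
    "allows_proliferation": true,
    "allows_loss": true
   },
   {
    "id": "B2",
    "label": "mature B (post-mitotic)",
    "level": 2,
    "column": "B",
    "observed": true,
    "is_tip": false,
    "allows_proliferation": false,
    "allows_loss": true
   }
  ],
  "edges": [
   {
    "source": "S",
    "target": "A1"
   },
   {
    "source": "S",
    "target": "B1"
   },
   {
    "source": "A1",
    "target": "B1"
   },
   {
    "source": "A1",
    "target": "A2"
   },
   {
    "source": "A1",
    "target": "B2"
   },
   {
    "source": "B1",
    "target": "B2"
   }
  ]
 },
 "rules": {
  "required_terminals": [
   "A2",
   "B2"
  ],
  "allow_reverse_column_change": true,
  "require_all_compartments_reachable": true,
  "mandatory_edges": [],
  "forbidden_edges": []
 },
 "default_rates": {
  "alpha": {
   "S>A1": 0.01,
   "S>B1": 0.005,
   "A1>B1": 0.45,
   "A1>A2": 0.3,
   "A1>B2": 0.42,
   "B1>B2": 0.3
  },
  "p": {
   "S": 0.015,
   "A1": 0.9,
   "B1": 0.02,
   "A2": 0.25
  },
  "delta": {
   "B1": 0.1,
   "A2": 1.15,
   "B2": 0.9
  },
  "N0": {
   "S": 0.01
  },
  "f0": {
   "S": 0.3
  }
 }
}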