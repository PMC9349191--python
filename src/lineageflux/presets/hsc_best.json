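{
 "topology": {
  "name": "hsc_best_model",
  "column_order": [
   "Sca1_hi",
   "Sca1_lo"
  ],
  "compartments": [
   {
    "id": "ES_HSC",
    "label": "CD201hi Sca-1hi HSC (tip)",
    "level": 0,
    "column": "Sca1_hi",
    "observed": true,
    "is_tip": true,
    "allows_proliferation": true,
    "allows_loss": false
   },
   {
    "id": "HSC_hi",
    "label": "CD201-/lo Sca-1hi HSC",
    "level": 1,
    "column": "Sca1_hi",
    "observed": true,
    "is_tip": false,
    "allows_proliferation": true,
    "allows_loss": false
   },
   {
    "id": "HSC_lo",
    "label": "CD201-/lo Sca-1lo HSC",
    "level": 1,
    "column": "Sca1_lo",
    "observed": true,
    "is_tip": false,
    "allows_proliferation": true,
    "allows_loss": true
   },
   {
    "id": "MPP_hi",
    "label": "Sca-1hi MPP",
    "level": 2,
    "column": "Sca1_hi",
    "observed": true,
    "is_tip": false,
    "allows_proliferation": true,
    "allows_loss": false
   },
   {
    "id": "MPP_lo",
    "label": "Sca-1lo MPP",
    "level": 2,
    "column": "Sca1_lo",
    "observed": true,
    "is_tip": false,
    "allows_proliferation": true,
    "allows_loss": false
   },
   {
    "id": "HPC1_hi",
    "label": "Sca-1hi HPC-1",
    "level": 3,
    "column": "Sca1_hi",
    "observed": true,
    "is_tip": false,
    "allows_proliferation": true,
    "allows_loss": false
   },
   {
    "id": "HPC1_lo",
    "label": "Sca-1lo HPC-1",
    "level": 3,
    "column": "Sca1_lo",
    "observed": true,
    "is_tip": false,
    "allows_proliferation": true,
    "allows_loss": false
   },
   {
    "id": "CLP",
    "label": "common lymphoid progenitor",
    "level": 4,
    "column": "Sca1_hi",
    "observed": true,
    "is_tip": false,
    "allows_proliferation": true,
    "allows_loss": true
   },
   {
    "id": "CMP",
    "label": "common myeloid progenitor",
    "level": 4,
    "column": "Sca1_lo",
    "observed": true,
    "is_tip": false,
    "allows_proliferation": true,
    "allows_loss": true
   }
  ],
  "edges": [
   {
    "source": "ES_HSC",
    "target": "HSC_hi"
   },
   {
    "source": "HSC_hi",
    "target": "MPP_hi"
   },
   {
    "source": "MPP_hi",
    "target": "HPC1_hi"
   },
   {
    "source": "HPC1_hi",
    "target": "CLP"
   },
   {
    "source": "MPP_lo",
    "target": "HPC1_lo"
   },
   {
    "source": "HPC1_lo",
    "target": "CMP"
   },
   {
    "source": "ES_HSC",
    "target": "HSC_lo"
   },
   {
    "source": "HSC_hi",
    "target": "HSC_lo"
   },
   {
    "source": "HSC_lo",
    "target": "MPP_lo"
   },
   {
    "source": "MPP_hi",
    "target": "MPP_lo"
   },
   {
    "source": "HPC1_hi",
    "target": "HPC1_lo"
   }
  ]
 },
 "rules": {
  "required_terminals": [
   "CMP",
   "CLP"
  ],
  "allow_reverse_column_change": false,
  "require_all_compartments_reachable": true,
  "mandatory_edges": [
   [
    "ES_HSC",
    "HSC_hi"
   ],
   [
    "HSC_hi",
    "MPP_hi"
   ],
   [
    "MPP_hi",
    "HPC1_hi"
   ],
   [
    "HPC1_hi",
    "CLP"
   ],
   [
    "MPP_lo",
    "HPC1_lo"
   ],
   [
    "HPC1_lo",
    "CMP"
   ],
   [
    "ES_HSC",
    "HSC_lo"
   ],
   [
    "HSC_hi",
    "HSC_lo"
   ],
   [
    "HSC_lo",
    "MPP_lo"
   ],
   [
    "MPP_hi",
    "MPP_lo"
   ],
   [
    "HPC1_hi",
    "HPC1_lo"
   ]
  ],
  "forbidden_edges": []
 },
 "default_rates": {
  "alpha": {
   "ES_HSC>HSC_hi": 0.008,
   "HSC_hi>MPP_hi": 0.06,
   "MPP_hi>HPC1_hi": 0.15,
   "HPC1_hi>CLP": 0.2,
   "MPP_lo>HPC1_lo": 0.3,
   "HPC1_lo>CMP": 0.6,
   "ES_HSC>HSC_lo": 0.004,
   "HSC_hi>HSC_lo": 0.03,
   "HSC_lo>MPP_lo": 0.04,
   "MPP_hi>MPP_lo": 0.1,
   "HPC1_hi>HPC1_lo": 0.15
  },
  "p": {
   "ES_HSC": 0.012,
   "HSC_hi": 0.04,
   "HSC_lo": 0.06,
   "MPP_hi": 0.15,
   "MPP_lo": 0.2,
   "HPC1_hi": 0.25,
   "HPC1_lo": 0.4,
   "CMP": 0.5,
   "CLP": 0.3
  },
  "delta": {
   "HSC_lo": 0.08,
   "CMP": 1.2,
   "CLP": 0.8
  },
  "N0": {
   "ES_HSC": 0.005
  },
  "f0": {
   "ES_HSC": 0.35
  }
 }
}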