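{
 "format": "logicfate-model/1",
 "name": "G1S-checkpoint",
 "metadata": {
  "description": "G1/S DNA-damage checkpoint cell-fate decision model",
  "p14ARF_variant": "default",
  "naming": "canonical spellings: cycle_arrest, CDK46CycD, CDK2CycE"
 },
 "components": [
  {
   "name": "SSB",
   "max_level": 2,
   "kind": "input"
  },
  {
   "name": "DSB",
   "max_level": 2,
   "kind": "input"
  },
  {
   "name": "ATM",
   "max_level": 2,
   "kind": "internal"
  },
  {
   "name": "ATR",
   "max_level": 2,
   "kind": "internal"
  },
  {
   "name": "CHEK1",
   "max_level": 1,
   "kind": "internal"
  },
  {
   "name": "CHEK2",
   "max_level": 1,
   "kind": "internal"
  },
  {
   "name": "p38MAPK",
   "max_level": 3,
   "kind": "internal"
  },
  {
   "name": "p14ARF",
   "max_level": 1,
   "kind": "internal"
  },
  {
   "name": "p16INK4a",
   "max_level": 2,
   "kind": "internal"
  },
  {
   "name": "Mdm2",
   "max_level": 1,
   "kind": "internal"
  },
  {
   "name": "p53",
   "max_level": 2,
   "kind": "internal"
  },
  {
   "name": "p21",
   "max_level": 1,
   "kind": "internal"
  },
  {
   "name": "CDC25A",
   "max_level": 2,
   "kind": "internal"
  },
  {
   "name": "E2F",
   "max_level": 1,
   "kind": "internal"
  },
  {
   "name": "RB1",
   "max_level": 1,
   "kind": "internal"
  },
  {
   "name": "CDK46CycD",
   "max_level": 1,
   "kind": "internal"
  },
  {
   "name": "CDK2CycE",
   "max_level": 1,
   "kind": "internal"
  },
  {
   "name": "proliferation",
   "max_level": 1,
   "kind": "output"
  },
  {
   "name": "apoptosis",
   "max_level": 1,
   "kind": "output"
  },
  {
   "name": "senescence",
   "max_level": 1,
   "kind": "output"
  },
  {
   "name": "cycle_arrest",
   "max_level": 1,
   "kind": "output"
  }
 ],
 "rules": [
  {
   "component": "ATM",
   "target": 1,
   "condition": "DSB = 1-2 AND NOT (DSB = 2-2)"
  },
  {
   "component": "ATM",
   "target": 2,
   "condition": "DSB = 2-2"
  },
  {
   "component": "ATR",
   "target": 1,
   "condition": "SSB = 1-2 AND NOT (SSB = 2-2)"
  },
  {
   "component": "ATR",
   "target": 2,
   "condition": "SSB = 2-2"
  },
  {
   "component": "CHEK2",
   "target": 1,
   "condition": "ATM = 2-2"
  },
  {
   "component": "CHEK1",
   "target": 1,
   "condition": "ATR = 2-2 OR ATM = 2-2"
  },
  {
   "component": "p38MAPK",
   "target": 1,
   "condition": "(ATM = 1-2 OR ATR = 1-2) AND NOT (ATM = 2-2)"
  },
  {
   "component": "p38MAPK",
   "target": 2,
   "condition": "ATM = 2-2 AND NOT (ATR = 2-2)"
  },
  {
   "component": "p38MAPK",
   "target": 3,
   "condition": "ATM = 2-2 AND ATR = 2-2"
  },
  {
   "component": "p14ARF",
   "target": 1,
   "condition": "p38MAPK = 3-3 OR E2F = 1-1"
  },
  {
   "component": "p16INK4a",
   "target": 1,
   "condition": "p38MAPK = 1-2"
  },
  {
   "component": "p16INK4a",
   "target": 2,
   "condition": "p38MAPK = 3-3"
  },
  {
   "component": "Mdm2",
   "target": 1,
   "condition": "p53 = 1-2 AND NOT (p14ARF = 1-1)"
  },
  {
   "component": "p53",
   "target": 1,
   "condition": "Mdm2 = 1-1 AND (p38MAPK = 3-3 OR ATR = 1-2 OR ATM = 1-2 OR CHEK1 = 1-1 OR CHEK2 = 1-1)"
  },
  {
   "component": "p53",
   "target": 2,
   "condition": "NOT (Mdm2 = 1-1) AND (p38MAPK = 3-3 OR ATR = 1-2 OR ATM = 1-2 OR CHEK1 = 1-1 OR CHEK2 = 1-1)"
  },
  {
   "component": "p21",
   "target": 1,
   "condition": "p53 = 1-2"
  },
  {
   "component": "CDC25A",
   "target": 1,
   "condition": "(p38MAPK = 1-3 OR CHEK2 = 1-1 OR CHEK1 = 1-1) AND NOT (p38MAPK = 1-3 AND CHEK2 = 1-1 AND CHEK1 = 1-1)"
  },
  {
   "component": "CDC25A",
   "target": 2,
   "condition": "NOT (p38MAPK = 1-3) AND NOT (CHEK2 = 1-1) AND NOT (CHEK1 = 1-1)"
  },
  {
   "component": "E2F",
   "target": 1,
   "condition": "NOT (RB1 = 1-1)"
  },
  {
   "component": "RB1",
   "target": 1,
   "condition": "NOT (CDK46CycD = 1-1) AND NOT (CDK2CycE = 1-1)"
  },
  {
   "component": "CDK46CycD",
   "target": 1,
   "condition": "CDC25A = 1-2 AND NOT (p16INK4a = 1-2) AND NOT (p21 = 1-1)"
  },
  {
   "component": "CDK2CycE",
   "target": 1,
   "condition": "NOT (p21 = 1-1) AND CDC25A = 2-2 AND E2F = 1-1"
  },
  {
   "component": "proliferation",
   "target": 1,
   "condition": "CDK2CycE = 1-1"
  },
  {
   "component": "apoptosis",
   "target": 1,
   "condition": "p53 = 2-2"
  },
  {
   "component": "senescence",
   "target": 1,
   "condition": "p16INK4a = 1-2 AND p21 = 1-1 AND NOT (CDC25A = 1-2) AND NOT (p53 = 2-2) OR p16INK4a = 2-2 AND p21 = 1-1 AND NOT (CDC25A = 2-2) AND NOT (p53 = 2-2)"
  },
  {
   "component": "cycle_arrest",
   "target": 1,
   "condition": "NOT (CDK2CycE = 1-1)"
  }
 ],
 "clamps": {}
}
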