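{
 "nodes": [
  {
   "name": "ADF",
   "layer": "sensory"
  },
  {
   "name": "ADL",
   "layer": "sensory"
  },
  {
   "name": "AFD",
   "layer": "sensory"
  },
  {
   "name": "ASH",
   "layer": "sensory"
  },
  {
   "name": "ASI",
   "layer": "sensory"
  },
  {
   "name": "ASJ",
   "layer": "sensory"
  },
  {
   "name": "ASK",
   "layer": "sensory"
  },
  {
   "name": "AWA",
   "layer": "sensory"
  },
  {
   "name": "AWC",
   "layer": "sensory"
  },
  {
   "name": "PHB",
   "layer": "sensory"
  },
  {
   "name": "AIY",
   "layer": "inter"
  },
  {
   "name": "AVA",
   "layer": "inter"
  },
  {
   "name": "AVB",
   "layer": "inter"
  },
  {
   "name": "PVN",
   "layer": "inter"
  },
  {
   "name": "RIA",
   "layer": "inter"
  },
  {
   "name": "CAN",
   "layer": "motor"
  },
  {
   "name": "RIV",
   "layer": "motor"
  },
  {
   "name": "RMD",
   "layer": "motor"
  },
  {
   "name": "SAB",
   "layer": "motor"
  },
  {
   "name": "SMB",
   "layer": "motor"
  },
  {
   "name": "SMD",
   "layer": "motor"
  },
  {
   "name": "VB",
   "layer": "motor"
  }
 ],
 "edges": [
  {
   "pre": "ADL",
   "post": "AVA",
   "EW": 25,
   "provenance": [
    "fixture"
   ]
  },
  {
   "pre": "ASH",
   "post": "AVA",
   "EW": 17,
   "provenance": [
    "fixture"
   ]
  },
  {
   "pre": "AWA",
   "post": "AVB",
   "EW": 14,
   "provenance": [
    "fixture"
   ]
  },
  {
   "pre": "ADF",
   "post": "AVB",
   "EW": 9,
   "provenance": [
    "fixture"
   ]
  },
  {
   "pre": "ASK",
   "post": "AIY",
   "EW": 21,
   "provenance": [
    "fixture"
   ]
  },
  {
   "pre": "AFD",
   "post": "AIY",
   "EW": 18,
   "provenance": [
    "fixture"
   ]
  },
  {
   "pre": "AWC",
   "post": "RIA",
   "EW": 22,
   "provenance": [
    "fixture"
   ]
  },
  {
   "pre": "ASI",
   "post": "RIA",
   "EW": 11,
   "provenance": [
    "fixture"
   ]
  },
  {
   "pre": "ASJ",
   "post": "PVN",
   "EW": 12,
   "provenance": [
    "fixture"
   ]
  },
  {
   "pre": "PHB",
   "post": "PVN",
   "EW": 10,
   "provenance": [
    "fixture"
   ]
  },
  {
   "pre": "ASH",
   "post": "RIV",
   "EW": 8,
   "provenance": [
    "fixture"
   ]
  },
  {
   "pre": "ADL",
   "post": "SMD",
   "EW": 7,
   "provenance": [
    "fixture"
   ]
  },
  {
   "pre": "PHB",
   "post": "CAN",
   "EW": 9,
   "provenance": [
    "fixture"
   ]
  },
  {
   "pre": "ASK",
   "post": "SMB",
   "EW": 6,
   "provenance": [
    "fixture"
   ]
  },
  {
   "pre": "AVA",
   "post": "RMD",
   "EW": 19,
   "provenance": [
    "fixture"
   ]
  },
  {
   "pre": "AVA",
   "post": "VB",
   "EW": 13,
   "provenance": [
    "fixture"
   ]
  },
  {
   "pre": "AVB",
   "post": "VB",
   "EW": 16,
   "provenance": [
    "fixture"
   ]
  },
  {
   "pre": "AVB",
   "post": "SAB",
   "EW": 8,
   "provenance": [
    "fixture"
   ]
  },
  {
   "pre": "AIY",
   "post": "SAB",
   "EW": 12,
   "provenance": [
    "fixture"
   ]
  },
  {
   "pre": "RIA",
   "post": "SMD",
   "EW": 15,
   "provenance": [
    "fixture"
   ]
  },
  {
   "pre": "PVN",
   "post": "CAN",
   "EW": 11,
   "provenance": [
    "fixture"
   ]
  }
 ]
}
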