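{
  "table2_flowmeters.csv": {
    "sha256": "2b8cc8e891284fc7c9784bfcd54bc05e282184cc51f9278d1f567b99ed71bb75",
    "rows": 48
  },
  "table3_activities.csv": {
    "sha256": "16f8bac7193df0092e1c0f38f8040cb6903f0ce03eada577dc9e83a0cfb8e967",
    "rows": 24
  },
  "table5_flows.csv": {
    "sha256": "a85189a109412b28a15de98414c67ff4bc9bd93645dfffed1250ce7a8c998623",
    "rows": 48
  }
}
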