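c3f6a89155c001be63cd49662f14a6cf98cd60a95fb36af475308b8c760175e6  table1.tsv
4eff84f57a6668ab4a430d9ec5b6562205777608733384b9d2043583ce7deedb  table2.tsv
d8dfad201db9e15edcbe95f6fc79c587e22f9be06f9df2e5fb8b49b4368b33b9  table3.tsv
a791a019e7892193fc5f6d4450c025a522d569d3b633d8c100c41134d0cea28f  table4.tsv
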