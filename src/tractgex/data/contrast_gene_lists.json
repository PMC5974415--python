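{
  "_note": "Genes called overexpressed per contrast in the published del/+ vs wild-type comparison. Column membership was reconstructed from the table's row-major rendering under the stated per-contrast counts (7/8/3/5); the reconstruction is consistent with the alphabetical ordering of each column and with the prose statement that exactly MVP, Sez6l2 and TAOK2 are exclusive to the male FA-increase contrast. Symbols are kept as printed (MVP vs panel symbol Mvp); matching is case-insensitive against the panel.",
  "male_increase": ["AI467606", "Gdpd3", "Kctd13", "MVP", "Qprt", "Sez6l2", "Taok2"],
  "male_decrease": ["4930451I11Rik", "AI467606", "Asphd1", "Doc2a", "Ino80e", "Ppp4c", "Qprt", "Spn"],
  "female_increase": ["4930451I11Rik", "AI467606", "Kif22"],
  "female_decrease": ["4930451I11Rik", "AI467606", "Asphd1", "Gdpd3", "Kctd13"]
}
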