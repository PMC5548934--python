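{
  "gene": "SATB2",
  "protein_length": 733,
  "exon_last_codon": [40, 60, 85, 120, 160, 180, 199, 330, 480, 620, 733],
  "domains": {
    "CUT1": [352, 437],
    "CUT2": [482, 560],
    "HOX": [614, 677]
  },
  "chrom": "chr2",
  "assembly": "hg19",
  "genomic_start": 200134223,
  "genomic_end": 200329831,
  "note": "Domain intervals and genomic coordinates are the published ones; exon boundaries in codon units are a packaged approximation constrained so that every located study variant falls in its stated exon (the true SATB2 exon structure is not reproduced)."
}
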