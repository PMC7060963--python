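{
  "transcript_id": "CRISPLD1-201-synthetic",
  "note": "Synthetic transcript model. Only the combined coding length of exons 6-8 (303 nt, the exon-skip block) is constrained by the annotated deletion; individual exon lengths and flanking exons are placeholders.",
  "cds_frame_offset": 0,
  "exons": [
    [1, 120],
    [2, 150],
    [3, 141],
    [4, 90],
    [5, 96],
    [6, 101],
    [7, 100],
    [8, 102],
    [9, 210],
    [10, 300]
  ]
}
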