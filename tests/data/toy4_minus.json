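{
 "gene": "TOY4",
 "strand": "-",
 "seqid": "toy4_minus_locus",
 "exons": [
  {
   "id": 1,
   "start": 310,
   "end": 370
  },
  {
   "id": 2,
   "start": 220,
   "end": 270
  },
  {
   "id": 3,
   "start": 120,
   "end": 175
  },
  {
   "id": 4,
   "start": 0,
   "end": 70
  }
 ],
 "alt_first_exon_ends": [],
 "annotated_start": {
  "exon_id": 1,
  "offset": 5
 }
}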