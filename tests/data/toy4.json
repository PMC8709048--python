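{
 "gene": "TOY4",
 "strand": "+",
 "seqid": "toy4_locus",
 "exons": [
  {
   "id": 1,
   "start": 0,
   "end": 60
  },
  {
   "id": 2,
   "start": 100,
   "end": 150
  },
  {
   "id": 3,
   "start": 195,
   "end": 250
  },
  {
   "id": 4,
   "start": 300,
   "end": 370
  }
 ],
 "alt_first_exon_ends": [],
 "annotated_start": {
  "exon_id": 1,
  "offset": 5
 }
}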