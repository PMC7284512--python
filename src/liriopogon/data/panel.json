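{
 "format_version": 1,
 "loci": {
  "rbcL": {
   "reference": "GTTACTATTCCAACGGTTGTAAGAAGCTGGCAAAGACATAATGTGTAGGTCGACCATCTGGGGACACATAGCTGATTTGAATGATGGCCAATCGCTACAATGCGTCGGCGTTATATTACTAGTGTAACACTGCATCTGGTTGCTCTACGTATGGGTCCAAATTAGCGGCTCCGAACTTTATTTGTAAAAAAGAGAGACTGTGGAGATTTACCAGTCTTATTAGGGAGGTTCTTTAAGAGTCACGACAGTCCGAACCATGCATAAAATACTGACTCGATTTGCAGTAAGTTAATGTTTTTCGATTTCCCATGCGTCTTCATTAGTTAATAAGCTATATACACCGCATTTACAAAGAATCAGAGCGGGCTTAAATTATAGCTACGAACTTTTGGGTCATATGCTAGATGTCTGGTCCGTCGAGTATATCCTGGAGGTACGGAGAATACTGGTCGTGGCGCTCCTGCTCTTCGACTGGGGGCACCCTCCCGTTCATCGATCCACTTCTCCGACGTATTCAGAGCGACGGATCCAACTGAACTCTGGTTCACCACGAAACTAATCACAATAGCCTATTGAGGTATTACATTTGGGGTGCGAAGCTTCAAACCTATGTCATAATGAATAGATAGAGTAATGCGCGCTGTCTGCATGATACTCCCAAAAACATCAGGAATCTAGTTAGCTAATCCTCACAAGTGGCGGGTGAGCAGTAGTCACGGGATTAAATTACACTAACGTCACTTATCTATACGGAACAAACCGCACTACTCTTCTAACGTACCATGATAACTATGAGCGTGTATCTTTACTTCTCCTCCCGAATGGTAAACTCCGAAGTCGACGACGGAGATAAATCGTTAGGGCCAAGAACAATCAGAATTGACAAAAGAATCCATGGGACGTTGGATAAGTTCAATTATCCGACAGGTTCCTGAATGAAGCTTAACTGTGATAGACTGACGAAAGCGCGATTCCTCTCGCGTATGCCAAGAGTTTTATA",
   "regions": {
    "rbcLa": [
     1,
     540
    ],
    "rbcLb": [
     541,
     1000
    ]
   }
  },
  "ITS": {
   "reference": "TTGGAGCAATTAACAAGCCAGCCCTCGCTCGTGAATACTAAAACGGATTGAGGCTCGAGGGCTGCCTAGGGTCCCTCGCTTATGACAGACCGTTCGACTATGCTCTAAGCAGCGGTAGTCGATGTTTAGACCGGTAACTGGGGCACTGACCGGTCCGTGCTCTCATCTGGATATTCATCACCCGTTACCTAGTCCGCTAAAGCTTTCACTGAGTTGTTCAGACTGGTCTTTCATAATGGGAACAGGGGACTAGATACGGTGCAGTAGACGGTGCGCCCCCCACCTTCGTCGCGTATGTGTCGCGGAATTGCGAGGGCCGCGCAGGTTAGCGCCCGGGGCGCGCGACACAGTCAGATACCACCGTCTAGCCTGACTTGTTGGACGTCCAGCTCGGCACGAACCTTTTGATGGGTCGGCCACCCTGGTAGACTAGTGTCCGACCTCCTATTGCAAACCTGTGAGAATCAAGCAGCTCGCGTTACCAACTGTGCCCCCGACCGGGAACCGTGACTTGCCGTCAAATGTACTGACGGCATCGGACAAATCCTAATGCCGATTCATCGTTTCTCCCCGTAACCTTTGGCCATCACCGACTTGGAT",
   "regions": {}
  }
 },
 "positions": [
  {
   "locus": "rbcL",
   "position": 172,
   "alleles": [
    "C",
    "G",
    "T"
   ]
  },
  {
   "locus": "rbcL",
   "position": 216,
   "alleles": [
    "C",
    "T"
   ]
  },
  {
   "locus": "rbcL",
   "position": 392,
   "alleles": [
    "A",
    "G"
   ]
  },
  {
   "locus": "rbcL",
   "position": 431,
   "alleles": [
    "A",
    "G"
   ]
  },
  {
   "locus": "rbcL",
   "position": 560,
   "alleles": [
    "C",
    "T"
   ]
  },
  {
   "locus": "rbcL",
   "position": 598,
   "alleles": [
    "A",
    "G"
   ]
  },
  {
   "locus": "rbcL",
   "position": 640,
   "alleles": [
    "A",
    "G"
   ]
  },
  {
   "locus": "rbcL",
   "position": 668,
   "alleles": [
    "C",
    "T"
   ]
  },
  {
   "locus": "rbcL",
   "position": 702,
   "alleles": [
    "A",
    "G"
   ]
  },
  {
   "locus": "rbcL",
   "position": 740,
   "alleles": [
    "A",
    "C"
   ]
  },
  {
   "locus": "rbcL",
   "position": 781,
   "alleles": [
    "C",
    "T"
   ]
  },
  {
   "locus": "rbcL",
   "position": 820,
   "alleles": [
    "A",
    "G"
   ]
  },
  {
   "locus": "rbcL",
   "position": 859,
   "alleles": [
    "C",
    "T"
   ]
  },
  {
   "locus": "rbcL",
   "position": 901,
   "alleles": [
    "C",
    "T"
   ]
  },
  {
   "locus": "rbcL",
   "position": 940,
   "alleles": [
    "A",
    "G"
   ]
  }
 ],
 "haplotypes": [
  {
   "name": "Type 1",
   "bases": {
    "172": "T",
    "216": "C",
    "392": "A",
    "431": "G",
    "560": "C",
    "598": "G",
    "640": "G",
    "668": "C",
    "702": "G",
    "740": "A",
    "781": "C",
    "820": "G",
    "859": "T",
    "901": "C",
    "940": "A"
   },
   "taxa": [
    "Ophiopogon japonicus (I)"
   ],
   "low_confidence": false
  },
  {
   "name": "Type 2",
   "bases": {
    "172": "C",
    "216": "C",
    "392": "G",
    "431": "G",
    "560": "T",
    "598": "A",
    "640": "G",
    "668": "C",
    "702": "G",
    "740": "A",
    "781": "C",
    "820": "G",
    "859": "T",
    "901": "C",
    "940": "A"
   },
   "taxa": [
    "Ophiopogon japonicus (II)",
    "Ophiopogon bodinieri",
    "Ophiopogon intermedius"
   ],
   "low_confidence": false
  },
  {
   "name": "Type 3",
   "bases": {
    "172": "C",
    "216": "T",
    "392": "G",
    "431": "G",
    "560": "T",
    "598": "A",
    "640": "A",
    "668": "C",
    "702": "G",
    "740": "A",
    "781": "C",
    "820": "G",
    "859": "T",
    "901": "C",
    "940": "A"
   },
   "taxa": [
    "Ophiopogon planiscapus",
    "Ophiopogon chingii"
   ],
   "low_confidence": false
  },
  {
   "name": "Type 4",
   "bases": {
    "172": "C",
    "216": "C",
    "392": "G",
    "431": "G",
    "560": "T",
    "598": "A",
    "640": "G",
    "668": "T",
    "702": "A",
    "740": "A",
    "781": "C",
    "820": "G",
    "859": "T",
    "901": "C",
    "940": "A"
   },
   "taxa": [
    "Ophiopogon longifolius"
   ],
   "low_confidence": true
  },
  {
   "name": "Type 5",
   "bases": {
    "172": "C",
    "216": "C",
    "392": "G",
    "431": "G",
    "560": "T",
    "598": "A",
    "640": "G",
    "668": "C",
    "702": "G",
    "740": "C",
    "781": "T",
    "820": "A",
    "859": "T",
    "901": "C",
    "940": "A"
   },
   "taxa": [
    "Ophiopogon jaburan"
   ],
   "low_confidence": false
  },
  {
   "name": "Type 6",
   "bases": {
    "172": "G",
    "216": "T",
    "392": "A",
    "431": "A",
    "560": "T",
    "598": "A",
    "640": "G",
    "668": "C",
    "702": "G",
    "740": "A",
    "781": "C",
    "820": "G",
    "859": "C",
    "901": "T",
    "940": "G"
   },
   "taxa": [
    "Liriope muscari",
    "Liriope spicata"
   ],
   "low_confidence": false
  }
 ],
 "consensus": "Type 2",
 "genus_position": {
  "locus": "rbcL",
  "position": 431,
  "genus_alleles": {
   "G": "Ophiopogon",
   "A": "Liriope"
  }
 },
 "its_triplet": {
  "locus": "ITS",
  "positions": [
   46,
   231,
   545
  ],
  "patterns": {
   "planiscapus": {
    "46": "A",
    "231": "C",
    "545": "C"
   },
   "bodinieri": {
    "46": "G",
    "231": "T",
    "545": "T"
   }
  },
  "species": {
   "planiscapus": "Ophiopogon planiscapus",
   "bodinieri": "Ophiopogon bodinieri"
  }
 }
}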