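{
 "locus": "A",
 "cutoff_angstrom": 4.0,
 "min_count": 5,
 "n_complexes": 111,
 "reconstructed": true,
 "cells": [
  [
   5,
   1,
   81
  ],
  [
   7,
   1,
   47
  ],
  [
   7,
   2,
   64
  ],
  [
   9,
   2,
   30
  ],
  [
   9,
   6,
   98
  ],
  [
   24,
   2,
   15
  ],
  [
   34,
   2,
   37
  ],
  [
   45,
   2,
   90
  ],
  [
   59,
   1,
   27
  ],
  [
   62,
   4,
   75
  ],
  [
   63,
   1,
   55
  ],
  [
   63,
   2,
   72
  ],
  [
   65,
   4,
   72
  ],
  [
   66,
   1,
   52
  ],
  [
   66,
   2,
   69
  ],
  [
   66,
   4,
   7
  ],
  [
   66,
   6,
   41
  ],
  [
   67,
   2,
   100
  ],
  [
   69,
   5,
   21
  ],
  [
   69,
   6,
   38
  ],
  [
   70,
   2,
   97
  ],
  [
   70,
   5,
   52
  ],
  [
   70,
   6,
   69
  ],
  [
   72,
   8,
   69
  ],
  [
   73,
   5,
   49
  ],
  [
   73,
   6,
   66
  ],
  [
   73,
   8,
   100
  ],
  [
   74,
   6,
   97
  ],
  [
   76,
   8,
   97
  ],
  [
   77,
   9,
   49
  ],
  [
   80,
   9,
   46
  ],
  [
   81,
   9,
   77
  ],
  [
   84,
   9,
   74
  ],
  [
   95,
   9,
   31
  ],
  [
   97,
   6,
   42
  ],
  [
   97,
   7,
   59
  ],
  [
   99,
   2,
   36
  ],
  [
   99,
   3,
   53
  ],
  [
   114,
   3,
   38
  ],
  [
   114,
   7,
   10
  ],
  [
   116,
   9,
   10
  ],
  [
   143,
   9,
   79
  ],
  [
   146,
   8,
   59
  ],
  [
   146,
   9,
   76
  ],
  [
   147,
   7,
   73
  ],
  [
   147,
   8,
   90
  ],
  [
   150,
   7,
   70
  ],
  [
   152,
   3,
   64
  ],
  [
   152,
   7,
   36
  ],
  [
   155,
   5,
   95
  ],
  [
   156,
   3,
   92
  ],
  [
   156,
   5,
   30
  ],
  [
   156,
   7,
   64
  ],
  [
   159,
   1,
   55
  ],
  [
   159,
   3,
   89
  ],
  [
   163,
   1,
   83
  ],
  [
   163,
   4,
   38
  ],
  [
   167,
   1,
   15
  ],
  [
   171,
   1,
   43
  ]
 ]
}
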