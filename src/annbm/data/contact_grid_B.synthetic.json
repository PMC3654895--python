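{
 "locus": "B",
 "cutoff_angstrom": 4.0,
 "min_count": 5,
 "n_complexes": 87,
 "reconstructed": true,
 "cells": [
  [
   5,
   1,
   21
  ],
  [
   7,
   1,
   5
  ],
  [
   7,
   2,
   22
  ],
  [
   9,
   2,
   6
  ],
  [
   9,
   6,
   74
  ],
  [
   24,
   2,
   81
  ],
  [
   34,
   2,
   79
  ],
  [
   45,
   1,
   13
  ],
  [
   45,
   2,
   30
  ],
  [
   46,
   2,
   61
  ],
  [
   59,
   1,
   57
  ],
  [
   62,
   4,
   45
  ],
  [
   63,
   1,
   25
  ],
  [
   63,
   2,
   42
  ],
  [
   65,
   4,
   60
  ],
  [
   66,
   1,
   40
  ],
  [
   66,
   2,
   57
  ],
  [
   66,
   4,
   13
  ],
  [
   66,
   6,
   47
  ],
  [
   67,
   2,
   10
  ],
  [
   69,
   4,
   28
  ],
  [
   69,
   5,
   45
  ],
  [
   69,
   6,
   62
  ],
  [
   70,
   2,
   25
  ],
  [
   70,
   5,
   76
  ],
  [
   70,
   6,
   15
  ],
  [
   72,
   8,
   33
  ],
  [
   73,
   5,
   13
  ],
  [
   73,
   6,
   30
  ],
  [
   73,
   8,
   64
  ],
  [
   74,
   6,
   61
  ],
  [
   76,
   5,
   28
  ],
  [
   76,
   8,
   79
  ],
  [
   77,
   9,
   49
  ],
  [
   80,
   9,
   64
  ],
  [
   81,
   9,
   17
  ],
  [
   84,
   9,
   32
  ],
  [
   95,
   9,
   61
  ],
  [
   97,
   3,
   21
  ],
  [
   97,
   6,
   72
  ],
  [
   97,
   7,
   11
  ],
  [
   99,
   2,
   66
  ],
  [
   99,
   3,
   5
  ],
  [
   114,
   3,
   80
  ],
  [
   114,
   7,
   70
  ],
  [
   116,
   9,
   10
  ],
  [
   118,
   9,
   72
  ],
  [
   123,
   9,
   71
  ],
  [
   124,
   9,
   24
  ],
  [
   143,
   9,
   67
  ],
  [
   146,
   8,
   65
  ],
  [
   146,
   9,
   82
  ],
  [
   147,
   7,
   79
  ],
  [
   147,
   8,
   18
  ],
  [
   147,
   9,
   35
  ],
  [
   150,
   5,
   60
  ],
  [
   150,
   7,
   16
  ],
  [
   150,
   8,
   33
  ],
  [
   152,
   3,
   10
  ],
  [
   152,
   6,
   61
  ],
  [
   152,
   7,
   78
  ],
  [
   155,
   4,
   42
  ],
  [
   155,
   5,
   59
  ],
  [
   155,
   7,
   15
  ],
  [
   155,
   8,
   32
  ],
  [
   156,
   3,
   56
  ],
  [
   156,
   5,
   12
  ],
  [
   156,
   7,
   46
  ],
  [
   159,
   1,
   37
  ],
  [
   159,
   3,
   71
  ],
  [
   163,
   1,
   5
  ],
  [
   163,
   4,
   56
  ],
  [
   167,
   1,
   51
  ],
  [
   170,
   1,
   66
  ],
  [
   171,
   1,
   19
  ]
 ]
}
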