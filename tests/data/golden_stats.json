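{
  "meta": {
    "oracle": "R 4.3.3",
    "n_fixtures": 60
  },
  "golden": [
    {
      "id": 0,
      "kind": "wilcoxon",
      "V": 125,
      "p": 0.325391948223114,
      "n": 25
    },
    {
      "id": 1,
      "kind": "paired_t",
      "t": -0.08137746660894517,
      "df": 21,
      "p": 0.935912383507194
    },
    {
      "id": 2,
      "kind": "welch_t",
      "t": 0.1954805162483726,
      "df": 6.709901608283955,
      "p": 0.8508039394706631
    },
    {
      "id": 3,
      "kind": "chisq",
      "chi2": 47.754098360655732,
      "df": 4,
      "p": 1.062008912935208e-09
    },
    {
      "id": 4,
      "kind": "binom",
      "p": 0.01707747162751422
    },
    {
      "id": 5,
      "kind": "correlation",
      "r": 0.5967693229715207
    },
    {
      "id": 6,
      "kind": "wilcoxon",
      "V": 21,
      "p": 0.7421875000000001,
      "n": 8
    },
    {
      "id": 7,
      "kind": "paired_t",
      "t": -1.445809742150491,
      "df": 8,
      "p": 0.1862414624061182
    },
    {
      "id": 8,
      "kind": "welch_t",
      "t": 3.015730646880155,
      "df": 10.156767565002992,
      "p": 0.01277485182258017
    },
    {
      "id": 9,
      "kind": "chisq",
      "chi2": 52.846153846153847,
      "df": 3,
      "p": 1.977182901167186e-11
    },
    {
      "id": 10,
      "kind": "binom",
      "p": 2.371692252312038e-19
    },
    {
      "id": 11,
      "kind": "correlation",
      "r": 0.6826668406196092
    },
    {
      "id": 12,
      "kind": "wilcoxon",
      "V": 25,
      "p": 0.09057617187500001,
      "n": 14
    },
    {
      "id": 13,
      "kind": "paired_t",
      "t": -0.9601475411725329,
      "df": 4,
      "p": 0.3913532900799856
    },
    {
      "id": 14,
      "kind": "welch_t",
      "t": 2.389887791183925,
      "df": 7.981152852405272,
      "p": 0.04393418130892299
    },
    {
      "id": 15,
      "kind": "chisq",
      "chi2": 4.567567567567568,
      "df": 1,
      "p": 0.0325827983856127
    },
    {
      "id": 16,
      "kind": "binom",
      "p": 3.090494990539718e-19
    },
    {
      "id": 17,
      "kind": "correlation",
      "r": 0.5633700771741397
    },
    {
      "id": 18,
      "kind": "wilcoxon",
      "V": 72,
      "p": 0.01355469226837158,
      "n": 25
    },
    {
      "id": 19,
      "kind": "paired_t",
      "t": -0.9917668126587278,
      "df": 25,
      "p": 0.3308140009227536
    },
    {
      "id": 20,
      "kind": "welch_t",
      "t": 2.329749199442906,
      "df": 21.170050814690914,
      "p": 0.02979148786373383
    },
    {
      "id": 21,
      "kind": "chisq",
      "chi2": 13.654320987654321,
      "df": 3,
      "p": 0.003415515892666514
    },
    {
      "id": 22,
      "kind": "binom",
      "p": 2.977302970952643e-14
    },
    {
      "id": 23,
      "kind": "correlation",
      "r": 0.5104211431867139
    },
    {
      "id": 24,
      "kind": "wilcoxon",
      "V": 9,
      "p": 0.004028320312500002,
      "n": 14
    },
    {
      "id": 25,
      "kind": "paired_t",
      "t": -0.9204843204638691,
      "df": 4,
      "p": 0.4094094223443748
    },
    {
      "id": 26,
      "kind": "welch_t",
      "t": 2.650815989292561,
      "df": 13.499894569966953,
      "p": 0.01946958660491242
    },
    {
      "id": 27,
      "kind": "chisq",
      "chi2": 17.478260869565219,
      "df": 2,
      "p": 0.0001601931257327879
    },
    {
      "id": 28,
      "kind": "binom",
      "p": 2.075368919604316e-13
    },
    {
      "id": 29,
      "kind": "correlation",
      "r": 0.6348967535900816
    },
    {
      "id": 30,
      "kind": "wilcoxon",
      "V": 61,
      "p": 0.03289413452148437,
      "n": 22
    },
    {
      "id": 31,
      "kind": "paired_t",
      "t": -0.1877669052972074,
      "df": 7,
      "p": 0.8563863205563512
    },
    {
      "id": 32,
      "kind": "welch_t",
      "t": 1.462542054017395,
      "df": 26.499067601964104,
      "p": 0.1553528427353295
    },
    {
      "id": 33,
      "kind": "chisq",
      "chi2": 9.227848101265822,
      "df": 1,
      "p": 0.002383616234838329
    },
    {
      "id": 34,
      "kind": "binom",
      "p": 7.432002272294959e-07
    },
    {
      "id": 35,
      "kind": "correlation",
      "r": 0.5640856579107251
    },
    {
      "id": 36,
      "kind": "wilcoxon",
      "V": 136,
      "p": 0.4907859563827514,
      "n": 25
    },
    {
      "id": 37,
      "kind": "paired_t",
      "t": -2.458147340259254,
      "df": 28,
      "p": 0.02041433619153029
    },
    {
      "id": 38,
      "kind": "welch_t",
      "t": 3.033729961026178,
      "df": 21.365650704233577,
      "p": 0.00623290684319059
    },
    {
      "id": 39,
      "kind": "chisq",
      "chi2": 48.658385093167702,
      "df": 4,
      "p": 6.879981544846437e-10
    },
    {
      "id": 40,
      "kind": "binom",
      "p": 0.0001919424135716908
    },
    {
      "id": 41,
      "kind": "correlation",
      "r": 0.638854885665706
    },
    {
      "id": 42,
      "kind": "wilcoxon",
      "V": 99,
      "p": 0.09031611680984496,
      "n": 25
    },
    {
      "id": 43,
      "kind": "paired_t",
      "t": 1.583709795366917,
      "df": 38,
      "p": 0.1215480245222263
    },
    {
      "id": 44,
      "kind": "welch_t",
      "t": 2.480811415363497,
      "df": 10.786070816207285,
      "p": 0.03091743415986303
    },
    {
      "id": 45,
      "kind": "chisq",
      "chi2": 19.840579710144926,
      "df": 1,
      "p": 8.417653831711143e-06
    },
    {
      "id": 46,
      "kind": "binom",
      "p": 8.83755632755875e-05
    },
    {
      "id": 47,
      "kind": "correlation",
      "r": 0.4047676201814217
    },
    {
      "id": 48,
      "kind": "wilcoxon",
      "V": 23,
      "p": 0.03533935546875001,
      "n": 15
    },
    {
      "id": 49,
      "kind": "paired_t",
      "t": -3.390741839454283,
      "df": 26,
      "p": 0.00223637851685309
    },
    {
      "id": 50,
      "kind": "welch_t",
      "t": 0.008364143036508861,
      "df": 8.720131092124239,
      "p": 0.9935146737653724
    },
    {
      "id": 51,
      "kind": "chisq",
      "chi2": 63.632653061224488,
      "df": 4,
      "p": 4.99384338103273e-13
    },
    {
      "id": 52,
      "kind": "binom",
      "p": 0.0001750328395918523
    },
    {
      "id": 53,
      "kind": "correlation",
      "r": 0.532931317219601
    },
    {
      "id": 54,
      "kind": "wilcoxon",
      "V": 57,
      "p": 0.003419220447540283,
      "n": 25
    },
    {
      "id": 55,
      "kind": "paired_t",
      "t": -1.232015677155008,
      "df": 34,
      "p": 0.2263959275641481
    },
    {
      "id": 56,
      "kind": "welch_t",
      "t": 0.2605338008251963,
      "df": 11.40617024628502,
      "p": 0.7990957690905722
    },
    {
      "id": 57,
      "kind": "chisq",
      "chi2": 20.223880597014926,
      "df": 3,
      "p": 0.0001525394120809886
    },
    {
      "id": 58,
      "kind": "binom",
      "p": 0.5957764574073554
    },
    {
      "id": 59,
      "kind": "correlation",
      "r": 0.5187031380050049
    }
  ]
}
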