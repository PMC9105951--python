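duration_pmf:
  0: 0.2600000000000002
  1: 0.08500000000000005
  2: 0.08500000000000005
  3: 0.07000000000000003
  4: 0.07000000000000003
  5: 0.07000000000000003
  6: 0.041666666666666685
  7: 0.041666666666666685
  8: 0.041666666666666685
  9: 0.041666666666666685
  10: 0.041666666666666685
  11: 0.041666666666666685
  12: 0.015714285714285726
  13: 0.015714285714285726
  14: 0.015714285714285726
  15: 0.015714285714285726
  16: 0.015714285714285726
  17: 0.015714285714285726
  18: 0.015714285714285726
overall_share:
  6: 0.46
  7: 0.63
  8: 0.554
  9: 0.478
  10: 0.402
  11: 0.326
  12: 0.25
  13: 0.23
  14: 0.21
  15: 0.19
  16: 0.17
  17: 0.15
  18: 0.13
  19: 0.122
  20: 0.114
  21: 0.106
  22: 0.098
  23: 0.09
servings_per_day: 1.0
share_consuming_by_tertile:
  1:
    6: 0.39
    7: 0.522649
    8: 0.454318
    9: 0.38646
    10: 0.319248
    11: 0.252943
    12: 0.18
    13: 0.172716
    14: 0.157469
    15: 0.142234
    16: 0.127017
    17: 0.111821
    18: 0.096652
    19: 0.090411
    20: 0.084146
    21: 0.077849
    22: 0.071505
    23: 0.06
  2:
    6: 0.49
    7: 0.664967
    8: 0.586827
    9: 0.508501
    10: 0.42992
    11: 0.350983
    12: 0.26
    13: 0.249789
    14: 0.228058
    15: 0.206328
    16: 0.184598
    17: 0.16287
    18: 0.141143
    19: 0.132444
    20: 0.123745
    21: 0.115044
    22: 0.106341
    23: 0.09
  3:
    6: 0.52
    7: 0.706681
    8: 0.624687
    9: 0.542401
    10: 0.459717
    11: 0.376473
    12: 0.28
    13: 0.269289
    14: 0.246158
    15: 0.22301
    16: 0.19984
    17: 0.176645
    18: 0.153416
    19: 0.14434
    20: 0.135294
    21: 0.126289
    22: 0.117342
    23: 0.1
tertile_weights:
- 0.326536
- 0.397655
- 0.275809
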