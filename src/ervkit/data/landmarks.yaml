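ltr_length: 780
pseudo_5p_anchor: 256
pseudo_3p_anchor: 326
landmarks:
  5ltr:
    start: 1
    end: 780
  leader:
    start: 781
    end: 2717
  gag:
    start: 2718
    end: 4191
  propol:
    start: 4195
    end: 7692
  env:
    start: 7720
    end: 9348
  3ltr:
    start: 9407
    end: 10186
  nc_zinc_finger_1:
    start: 4021
    end: 4062
  nc_zinc_finger_2:
    start: 4093
    end: 4131
  gpy_f:
    start: 7501
    end: 7527
  env_island:
    start: 8289
    end: 8318
recurrent_deletions:
- start: 2780
  end: 3209
- start: 4513
  end: 6184
- start: 6797
  end: 7692
- start: 7928
  end: 9114
pbs_window:
  start: 4
  end: 21
gene_windows:
  gag:
    start: 2718
    end: 4191
  pro:
    start: 4195
    end: 5187
  pol_rt:
    start: 5188
    end: 6700
  pol_in:
    start: 6701
    end: 7692
  env:
    start: 7720
    end: 9348
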