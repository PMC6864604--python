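{
  "description": "Published test-set confusion matrix of the smartphone LFA readout study (rows = actual class, columns = predicted class, both ordered 100 pg, 10 pg, 1 pg, 100 fg, 10 fg).",
  "labels_fg": [100000, 10000, 1000, 100, 10],
  "counts": [
    [10, 0, 0, 0, 0],
    [1, 9, 0, 0, 0],
    [0, 0, 10, 0, 0],
    [0, 0, 0, 10, 0],
    [0, 0, 0, 0, 10]
  ]
}
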