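[
  {"url": "/das/sources", "status": 200, "das_status": "OK"},
  {"url": "/das/sources/demo", "status": 200, "das_status": "OK"},
  {"url": "/das/sources/ref", "status": 200, "das_status": "OK"},
  {"url": "/das/sources/nosuch", "status": 404, "das_status": "BAD_DATA_SOURCE"},
  {"url": "/das/demo/features?segment=seg000", "status": 200, "das_status": "OK"},
  {"url": "/das/demo/features?segment=seg000:1,500", "status": 200, "das_status": "OK"},
  {"url": "/das/demo/features?segment=seg000:100,900;type=exon", "status": 200, "das_status": "OK"},
  {"url": "/das/demo/features?segment=seg000:100,900;type=exon;category=transcription", "status": 200, "das_status": "OK"},
  {"url": "/das/demo/features?segment=seg000;segment=seg001", "status": 200, "das_status": "OK"},
  {"url": "/das/demo/features?segment=chrZZ", "status": 200, "das_status": "OK"},
  {"url": "/das/demo/features?feature_id=f0_1", "status": 200, "das_status": "OK"},
  {"url": "/das/demo/features?segment=seg000:900,100", "status": 400, "das_status": "BAD_COMMAND_ARGS"},
  {"url": "/das/demo/features?segment=seg000:x,y", "status": 400, "das_status": "BAD_COMMAND_ARGS"},
  {"url": "/das/demo/features", "status": 400, "das_status": "BAD_COMMAND_ARGS"},
  {"url": "/das/demo/types", "status": 200, "das_status": "OK"},
  {"url": "/das/demo/types?segment=seg001:1,2000", "status": 200, "das_status": "OK"},
  {"url": "/das/demo/entry_points", "status": 200, "das_status": "OK"},
  {"url": "/das/demo/entry_points?rows=1-2", "status": 200, "das_status": "OK"},
  {"url": "/das/demo/entry_points?rows=5-9", "status": 200, "das_status": "OK"},
  {"url": "/das/demo/entry_points?rows=9-2", "status": 400, "das_status": "BAD_COMMAND_ARGS"},
  {"url": "/das/demo/stylesheet", "status": 200, "das_status": "OK"},
  {"url": "/das/demo/sequence?segment=seg000", "status": 400, "das_status": "BAD_COMMAND"},
  {"url": "/das/demo/nosuchcommand", "status": 400, "das_status": "BAD_COMMAND"},
  {"url": "/das/nosuch/features?segment=chr1", "status": 404, "das_status": "BAD_DATA_SOURCE"},
  {"url": "/das/ref/sequence?segment=seg000", "status": 200, "das_status": "OK"},
  {"url": "/das/ref/sequence?segment=seg000:10,50", "status": 200, "das_status": "OK"},
  {"url": "/das/ref/sequence?segment=chrZZ", "status": 404, "das_status": "BAD_REFERENCE_OBJECT"},
  {"url": "/das/ref/sequence?segment=seg000:1,99999", "status": 404, "das_status": "BAD_REFERENCE_OBJECT"},
  {"url": "/das/ref/entry_points", "status": 200, "das_status": "OK"},
  {"url": "/das/ref/stylesheet", "status": 400, "das_status": "BAD_COMMAND"},
  {"url": "/notdas/x", "status": 400, "das_status": "BAD_COMMAND"}
]
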