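stage: inputs
error: input file not found: /tmp/pytest-of-root/pytest-2/test_missing_obesity_file_exit0/obesity.csv (obesity)
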