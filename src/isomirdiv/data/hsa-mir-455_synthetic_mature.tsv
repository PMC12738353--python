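precursor_id	mirna	start	end
hsa-mir-455-synthetic	miR-455-5p	9	30
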