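>hsa-mir-455-synthetic synthetic hairpin; mature 5p arm is the authentic hsa-miR-455-5p sequence, flanks and 3p arm are constructed
GCAUCACGUAUGUGCCUUUGGACUACAUCGUGGAUUUAGCCACGAUGUAGUCCAAAGGCACAUACUGCUU
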