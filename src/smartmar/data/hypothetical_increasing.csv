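attribute,kind,level_label,level_value,weight,ci_lower,ci_upper
AE1,risk,0%,0,7.5,,
AE1,risk,3%,3,7,,
AE1,risk,6%,6,6,,
AE1,risk,10%,10,4,,
AE1,risk,15%,15,0,,
AE2,risk,0%,0,7.5,,
AE2,risk,3%,3,7,,
AE2,risk,6%,6,6,,
AE2,risk,10%,10,4,,
AE2,risk,15%,15,0,,
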