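attribute,kind,level_label,level_value,weight,ci_lower,ci_upper
physical functioning,benefit,NYHA I,,10,9.46,10.54
physical functioning,benefit,NYHA II,,9.28,8.81,9.74
physical functioning,benefit,NYHA III,,7.75,7.37,8.14
physical functioning,benefit,NYHA IV,,0.00,-0.95,0.95
hospitalizations,benefit,2,,0.34,0.08,0.60
hospitalizations,benefit,3,,1.12,0.82,1.41
hospitalizations,benefit,5,,0,-0.25,0.25
device,benefit,Device,,7.28,6.47,8.08
device,benefit,No device,,0,-0.81,0.81
30-day death,risk,1%,1,0,-0.51,0.51
30-day death,risk,2%,2,-0.36,-0.81,0.09
30-day death,risk,4%,4,-2.61,-2.98,-2.23
30-day death,risk,7%,7,-5.35,-6.02,-4.68
30-day death,risk,10%,10,-7.29,-8.06,-6.52
severe bleeding,risk,1%,1,0,-0.45,0.45
severe bleeding,risk,2%,2,0.49,0.09,0.89
severe bleeding,risk,4%,4,-1.12,-1.49,-0.76
severe bleeding,risk,7%,7,-2.80,-3.34,-2.25
severe bleeding,risk,10%,10,-3.61,-4.21,-3.00
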