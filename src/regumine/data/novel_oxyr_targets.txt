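yaaA
yaeH
yaiA
ybjC
ybjM
ydcH
ydeN
yfiA
ygaQ
ygaR
yhjA
yljA
ytfK
hemF-rcsC
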