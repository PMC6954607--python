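# 14 commonly used Arabidopsis reference (housekeeping) genes, TAIR IDs
# ACT2
AT3G18780
# ACT7
AT5G09810
# ACT8
AT1G49240
# APT1
AT1G27450
# EF1a
AT5G60390
# eIF4A
AT3G13920
# NDUFA8
AT5G18800
# TUB2
AT5G62690
# TUB6
AT5G12250
# TUB9
AT4G20890
# UBQ4
AT5G20620
# UBQ5
AT3G62250
# UBQ10
AT4G05320
# UBQ11
AT4G05050
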