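>IGHV3-3*01_framework germline=IGHV3-3*01
EVQLVESGGGLVQPGGSLRLSCAASGRTFSYNPMGWFRQAPGKGRELVAAISRTGGSTYY
PDSVEGRFTISRDNAKRMVYLQMNSLRAEDTAVYYCAAAGVRAEDGRVRTLPSEYTFWGQ
GTQVTVSS
>IGHV3S53*01_framework germline=IGHV3S53*01
EVQLLESGGGEVQPGGSLRLSCAASGFSFSINAMGWYRQAPGKRREFVAAIESGRNTVYA
ESVKGRFTISRDNAKNTVYLQMSSLRAEDTAVYYCGLLKGNRVVSPSVAYWGQGTLVTVK
P
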