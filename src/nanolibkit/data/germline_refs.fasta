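>IGHV3-3*01
EVQLVESGGGLVQPGGSLRLSCAASGRTFSYNPMGWFRQAPGKGRELVAAISRTGGSTYY
PDSVEGRFTISRDNAKRMVYLQMNSLRAEDTAVYYC
>IGHV3S53*01
EVQLLESGGGEVQPGGSLRLSCAASGFSFSINAMGWYRQAPGKRREFVAAIESGRNTVYA
ESVKGRFTISRDNAKNTVYLQMSSLRAEDTAVYYC
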