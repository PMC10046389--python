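>CALRm_A_synthetic class=A notation=p.L367Tfs*46 note=synthetic stand-in tail; wild-type prefix 352-366, novel tail matches published length/charge/CREAC features
AAEKQMKDKQDEEQRTRMRTRSRMRARMRTRSRMRARMRTRSRMRARMTSTSCREACQGW
>CALRm_B_synthetic class=B notation=p.K385Nfs*47 note=synthetic stand-in tail; wild-type prefix 352-384, novel tail matches published length/charge/CREAC features
AAEKQMKDKQDEEQRLKEEEEDKKRKEEEEAEDNRMRTRSRMRARMRTRSRMRARMRTRSRMRARMTSMTSCREACQGW
>CALRm_C_synthetic class=C notation=p.E380Dfs*51 note=synthetic stand-in tail; wild-type prefix 352-379, novel tail matches published length/charge/CREAC features
AAEKQMKDKQDEEQRLKEEEEDKKRKEEDRMRTRSRMRARMRTRSRMRARMRTRSRMRARMRTRSRMATSCREACQGW
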