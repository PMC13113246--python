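# Step-FIS rule base: error / rate-of-change antecedents, crisp Sugeno
# consequents (Increase=+1, Maintain=0, Decrease=-1) and rule weights.
rule,error,rate,output,weight
1,Negative,Zero,Increase,1.00
2,Negative,Negative,Increase,1.00
3,Any,Positive,Maintain,1.00
4,Positive,Any,Decrease,0.75
5,Zero,Any,Maintain,1.00
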