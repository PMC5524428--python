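ACGTACGTAC  GTACGTACGT
    ......  ....>     
     ..G..  .DD..>    
      <...II....      
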