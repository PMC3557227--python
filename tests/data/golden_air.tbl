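assign ( resid 53 and segid A)
       (
        ( resid 4 and segid B)
     or
        ( resid 6 and segid B)
     or
        ( resid 8 and segid B)
     or
        ( resid 44 and segid B)
     or
        ( resid 48 and segid B)
     or
        ( resid 68 and segid B)
     or
        ( resid 70 and segid B)
       ) 2.0 2.0 0.0

assign ( resid 54 and segid A)
       (
        ( resid 4 and segid B)
     or
        ( resid 6 and segid B)
     or
        ( resid 8 and segid B)
     or
        ( resid 44 and segid B)
     or
        ( resid 48 and segid B)
     or
        ( resid 68 and segid B)
     or
        ( resid 70 and segid B)
       ) 2.0 2.0 0.0

assign ( resid 79 and segid A)
       (
        ( resid 4 and segid B)
     or
        ( resid 6 and segid B)
     or
        ( resid 8 and segid B)
     or
        ( resid 44 and segid B)
     or
        ( resid 48 and segid B)
     or
        ( resid 68 and segid B)
     or
        ( resid 70 and segid B)
       ) 2.0 2.0 0.0

assign ( resid 99 and segid A)
       (
        ( resid 4 and segid B)
     or
        ( resid 6 and segid B)
     or
        ( resid 8 and segid B)
     or
        ( resid 44 and segid B)
     or
        ( resid 48 and segid B)
     or
        ( resid 68 and segid B)
     or
        ( resid 70 and segid B)
       ) 2.0 2.0 0.0

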