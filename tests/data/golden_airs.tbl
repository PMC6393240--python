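assign ( resid 17 and segid A )
       (
        ( resid 129 and segid B )
     or
        ( resid 130 and segid B )
     or
        ( resid 131 and segid B )
       ) 2.0 0.0 0.0
!
assign ( resid 20 and segid A )
       (
        ( resid 129 and segid B )
     or
        ( resid 130 and segid B )
     or
        ( resid 131 and segid B )
       ) 2.0 0.0 0.0
!
assign ( resid 23 and segid A )
       (
        ( resid 129 and segid B )
     or
        ( resid 130 and segid B )
     or
        ( resid 131 and segid B )
       ) 2.0 0.0 0.0
!
assign ( resid 129 and segid B )
       (
        ( resid 16 and segid A )
     or
        ( resid 17 and segid A )
     or
        ( resid 20 and segid A )
     or
        ( resid 21 and segid A )
     or
        ( resid 23 and segid A )
       ) 2.0 0.0 0.0
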