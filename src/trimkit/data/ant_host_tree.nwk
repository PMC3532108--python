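(Apis_mellifera,(Linepithema_humile,((Camponotus_pennsylvanicus,(Lasius_alienus,Lasius_neoniger)),((Pogonomyrmex_barbatus,Pogonomyrmex_rugosus),((Aphaenogaster_rudis,Messor_pergandei),(Crematogaster_sp,(Solenopsis_xyloni,(Pheidole_desertorum,Pheidole_hyatti))))))));
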