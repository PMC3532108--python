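taxon	state
Apis_mellifera	absent
Linepithema_humile	present
Camponotus_pennsylvanicus	absent
Lasius_alienus	present
Lasius_neoniger	present
Pogonomyrmex_barbatus	present
Pogonomyrmex_rugosus	present
Aphaenogaster_rudis	absent
Messor_pergandei	absent
Crematogaster_sp	absent
Solenopsis_xyloni	absent
Pheidole_desertorum	present
Pheidole_hyatti	present
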