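genome_id	has_glnrs	has_glurs2	has_gatcab	trna_gln_1_72	pzbd_deleted
Acholeplasma_laidlawii	true	false	false	GC	true
Phytoplasma_mali	true	false	false	GC	true
Onion_yellows_phytoplasma	true	false	false	GC	true
Neorickettsia_sennetsu	false	true	true	UA	true
Akkermansia_muciniphila	true	false	true	GC	true
Phycisphaera_mikurensis	true	false	true	GC	true
Methylacidiphilum_infernorum	false	false	true	AU	true
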