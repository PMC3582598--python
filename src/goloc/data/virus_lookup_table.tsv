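# Explicit cellular-component GO terms for the six viral-protein
# location classes: per class one essential term plus its direct
# is_a/part_of child terms ("occurs in" children are excluded).
# class	go_id	role	relationship
Viral capsid	GO:0019028	essential	-
Viral capsid	GO:0046727	child	part_of
Viral capsid	GO:0046798	child	part_of
Viral capsid	GO:0046806	child	part_of
Viral capsid	GO:0019013	child	part_of
Viral capsid	GO:0019029	child	is_a
Viral capsid	GO:0019030	child	is_a
Host cell membrane	GO:0033644	essential	-
Host cell membrane	GO:0044155	child	part_of
Host cell membrane	GO:0044084	child	part_of
Host cell membrane	GO:0044385	child	part_of
Host cell membrane	GO:0044160	child	is_a
Host cell membrane	GO:0044162	child	is_a
Host cell membrane	GO:0085037	child	is_a
Host cell membrane	GO:0085042	child	is_a
Host cell membrane	GO:0085039	child	is_a
Host cell membrane	GO:0020002	child	is_a
Host cell membrane	GO:0044167	child	is_a
Host cell membrane	GO:0044173	child	is_a
Host cell membrane	GO:0044175	child	is_a
Host cell membrane	GO:0044178	child	is_a
Host cell membrane	GO:0044384	child	is_a
Host cell membrane	GO:0033645	child	is_a
Host cell membrane	GO:0044231	child	is_a
Host cell membrane	GO:0044188	child	is_a
Host cell membrane	GO:0044191	child	is_a
Host cell membrane	GO:0044200	child	is_a
Host ER	GO:0044165	essential	-
Host ER	GO:0044166	child	part_of
Host ER	GO:0044167	child	part_of
Host ER	GO:0044168	child	is_a
Host ER	GO:0044170	child	is_a
Host cytoplasm	GO:0030430	essential	-
Host cytoplasm	GO:0033655	child	part_of
Host nucleus	GO:0042025	essential	-
Host nucleus	GO:0044094	child	part_of
Secreted	GO:0005576	essential	-
Secreted	GO:0048046	child	is_a
Secreted	GO:0044421	child	part_of
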