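accession_id	collection	original_label	true_species	rbcl_type	its_clade	triplet	source
BTG_624	Liriope	Liriope exiliflora	Liriope muscari	Type 6	Liriope-muscari		recorded
BTG_625	Liriope	Liriope graminifolia	Liriope spicata	Type 6	Liriope-spicata		recorded
BTG_626	Liriope	Liriope graminifolia	Liriope spicata	Type 6	Liriope-spicata		recorded
BTG_627	Liriope	Liriope graminifolia	Liriope spicata	Type 6	Liriope-spicata		recorded
BTG_630	Liriope	Liriope graminifolia	Liriope spicata	Type 6	Liriope-spicata		recorded
BTG_628	Liriope	Liriope graminifolia	Ophiopogon planiscapus	Type 3	B3a	planiscapus	recorded
BTG_667	Liriope	Liriope muscari	Ophiopogon jaburan	Type 5	jaburan-branch		recorded
BTG_677	Liriope	Liriope muscari	Ophiopogon planiscapus	Type 3	B3a	planiscapus	recorded
BTG_601	Liriope	Liriope muscari	Liriope muscari	Type 6	Liriope-muscari		reconstructed
BTG_602	Liriope	Liriope muscari	Liriope muscari	Type 6	Liriope-muscari		reconstructed
BTG_603	Liriope	Liriope muscari	Liriope muscari	Type 6	Liriope-muscari		reconstructed
BTG_604	Liriope	Liriope muscari	Liriope muscari	Type 6	Liriope-muscari		reconstructed
BTG_605	Liriope	Liriope muscari	Liriope muscari	Type 6	Liriope-muscari		reconstructed
BTG_606	Liriope	Liriope muscari	Liriope muscari	Type 6	Liriope-muscari		reconstructed
BTG_607	Liriope	Liriope muscari	Liriope muscari	Type 6	Liriope-muscari		reconstructed
BTG_608	Liriope	Liriope muscari	Liriope muscari	Type 6	Liriope-muscari		reconstructed
BTG_609	Liriope	Liriope muscari	Liriope muscari	Type 6	Liriope-muscari		reconstructed
BTG_610	Liriope	Liriope muscari	Liriope muscari	Type 6	Liriope-muscari		reconstructed
BTG_611	Liriope	Liriope muscari	Liriope muscari	Type 6	Liriope-muscari		reconstructed
BTG_612	Liriope	Liriope muscari	Liriope muscari	Type 6	Liriope-muscari		reconstructed
BTG_613	Liriope	Liriope muscari	Liriope muscari	Type 6	Liriope-muscari		reconstructed
BTG_614	Liriope	Liriope muscari	Liriope muscari	Type 6	Liriope-muscari		reconstructed
BTG_615	Liriope	Liriope muscari	Liriope muscari	Type 6	Liriope-muscari		reconstructed
BTG_616	Liriope	Liriope muscari	Liriope muscari	Type 6	Liriope-muscari		reconstructed
BTG_617	Liriope	Liriope muscari	Liriope muscari	Type 6	Liriope-muscari		reconstructed
BTG_618	Liriope	Liriope muscari	Liriope muscari	Type 6	Liriope-muscari		reconstructed
BTG_619	Liriope	Liriope muscari	Liriope muscari	Type 6	Liriope-muscari		reconstructed
BTG_620	Liriope	Liriope muscari	Liriope muscari	Type 6	Liriope-muscari		reconstructed
BTG_621	Liriope	Liriope muscari	Liriope muscari	Type 6	Liriope-muscari		reconstructed
BTG_622	Liriope	Liriope muscari	Liriope muscari	Type 6	Liriope-muscari		reconstructed
BTG_623	Liriope	Liriope muscari	Liriope muscari	Type 6	Liriope-muscari		reconstructed
BTG_629	Liriope	Liriope muscari	Liriope muscari	Type 6	Liriope-muscari		reconstructed
BTG_631	Liriope	Liriope muscari	Liriope muscari	Type 6	Liriope-muscari		reconstructed
BTG_632	Liriope	Liriope muscari	Liriope muscari	Type 6	Liriope-muscari		reconstructed
BTG_633	Liriope	Liriope muscari	Liriope spicata	Type 6	Liriope-spicata		reconstructed
BTG_634	Liriope	Liriope muscari	Liriope spicata	Type 6	Liriope-spicata		reconstructed
BTG_635	Liriope	Liriope muscari	Liriope spicata	Type 6	Liriope-spicata		reconstructed
BTG_636	Liriope	Liriope muscari	Liriope spicata	Type 6	Liriope-spicata		reconstructed
BTG_637	Liriope	Liriope muscari	Liriope spicata	Type 6	Liriope-spicata		reconstructed
BTG_638	Liriope	Liriope muscari	Liriope spicata	Type 6	Liriope-spicata		reconstructed
BTG_639	Liriope	Liriope minor	Liriope muscari	Type 6	Liriope-muscari		reconstructed
BTG_640	Liriope	Liriope minor	Liriope muscari	Type 6	Liriope-muscari		reconstructed
BTG_641	Liriope	Liriope minor	Liriope muscari	Type 6	Liriope-muscari		reconstructed
BTG_642	Liriope	Liriope spicata	Liriope muscari	Type 6	Liriope-muscari		reconstructed
BTG_643	Liriope	Liriope spicata	Liriope muscari	Type 6	Liriope-muscari		reconstructed
BTG_644	Liriope	Liriope spicata	Liriope muscari	Type 6	Liriope-muscari		reconstructed
BTG_678	Ophiopogon	Ophiopogon bodinieri	Ophiopogon bodinieri	Type 2	B3b	bodinieri	recorded
BTG_679	Ophiopogon	Ophiopogon chingii	Ophiopogon japonicus (II)	Type 2	B2		recorded
BTG_680	Ophiopogon	Ophiopogon clarkei	Ophiopogon bodinieri	Type 2	B3b	bodinieri	recorded
BTG_682	Ophiopogon	Ophiopogon intermedius	Ophiopogon japonicus (I)	Type 1	B2		recorded
BTG_683	Ophiopogon	Ophiopogon intermedius	Ophiopogon japonicus (I)	Type 1	B2		recorded
BTG_684	Ophiopogon	Ophiopogon intermedius	Ophiopogon japonicus (I)	Type 1	B2		recorded
BTG_685	Ophiopogon	Ophiopogon jaburan	Ophiopogon jaburan	Type 5	jaburan-branch		recorded
BTG_686	Ophiopogon	Ophiopogon jaburan	Ophiopogon bodinieri	Type 2	B3b	bodinieri	recorded
BTG_688	Ophiopogon	Ophiopogon japonicus	Ophiopogon japonicus (I)	Type 1	B2		recorded
BTG_691	Ophiopogon	Ophiopogon japonicus	Ophiopogon japonicus (I)	Type 1	B2		recorded
BTG_692	Ophiopogon	Ophiopogon japonicus	Ophiopogon japonicus (I)	Type 1	B2		recorded
BTG_690	Ophiopogon	Ophiopogon japonicus	Ophiopogon planiscapus	Type 3	B3b	planiscapus	recorded
BTG_693	Ophiopogon	Ophiopogon japonicus	Liriope muscari	Type 6	Liriope-muscari		recorded
BTG_695	Ophiopogon	Ophiopogon japonicus	Liriope muscari	Type 6	Liriope-muscari		recorded
BTG_697	Ophiopogon	Ophiopogon planiscapus	Ophiopogon planiscapus	Type 3	B3a	planiscapus	recorded
BTG_698	Ophiopogon	Ophiopogon bodinieri	Ophiopogon planiscapus	Type 3	B3a	planiscapus	reconstructed
BTG_699	Ophiopogon	Ophiopogon jaburan	Ophiopogon planiscapus	Type 3	B3b	planiscapus	reconstructed
BTG_700	Ophiopogon	Ophiopogon planiscapus	Ophiopogon planiscapus	Type 3	B3a	planiscapus	recorded
BTG_701	Ophiopogon	Ophiopogon planiscapus	Ophiopogon planiscapus	Type 3	B3a	planiscapus	recorded
BTG_702	Ophiopogon	Ophiopogon planiscapus	Ophiopogon planiscapus	Type 3	B3a	planiscapus	recorded
BTG_703	Ophiopogon	Ophiopogon sp.	Ophiopogon bodinieri	Type 2	B3a	bodinieri	recorded
BTG_704	Ophiopogon	Ophiopogon wallichianus	Ophiopogon bodinieri	Type 2	B3a	bodinieri	recorded
BTG_705	Ophiopogon	Ophiopogon sp.	Ophiopogon japonicus (I)	Type 1	B2		recorded
BTG_706	Ophiopogon	Ophiopogon sp.	Ophiopogon japonicus (I)	Type 1	B2		recorded
BTG_708	Ophiopogon	Ophiopogon sp.	Ophiopogon japonicus (I)	Type 1	B2		recorded
BTG_709	Ophiopogon	Ophiopogon sp.	Liriope muscari	Type 6	Liriope-muscari		recorded
BTG_711	Ophiopogon	Ophiopogon sp.	Liriope muscari	Type 6	Liriope-muscari		recorded
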