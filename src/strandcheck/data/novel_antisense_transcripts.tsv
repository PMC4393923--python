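transcript	chrom	strand	txStart	txEnd	exonStarts	exonEnds	read_count
NAG0001-1	chr19	-	50361371	50362420	50361371,50362099,	50361883,50362420,	180
NAG0001-2	chr19	-	50361659	50362420	50361659,50361810,50362099,	50361684,50361883,50362420,	34
NAG0002-1	chr19	-	50362914	50364190	50362914,	50364190,	121
NAG0002-2	chr19	-	50362914	50364190	50362914,50363498,	50363413,50364190,	125.5
NAG0003-1	chr5	+	477198	477618	477198,	477618,	90.5
NAG0003-2	chr5	+	477198	478103	477198,477920,	477580,478103,	102.5
NAG0004-1	chr2	-	113341899	113342061	113341899,	113342061,	5
NAG0004-2	chr2	-	113342043	113342358	113342043,113342247,	113342090,113342358,	17
NAG0005-1	chr2	-	75157511	75186055	75157511,75185858,	75158170,75186055,	223
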