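species	code	chromosome_2n	two_C_pg	nx	one_Cx_pg
B. distachyon	Bdis_Bd21-3	10	0.631	2	0.316
B. stacei	Bsta_ABR114	20	0.564	2	0.282
B. hybridum	Bhyb_ABR113	30	1.265	4	0.633
B. arbuscula	Barb502	18	0.713	2	0.357
B. boissieri	Bboi3	48	3.236	6	0.539
B. boissieri	Bboi10	48	3.152	6	0.525
B. boissieri	Bboi15	48	3.149	6	0.525
B. mexicanum	Bmex347	40	3.774	4	0.944
B. mexicanum	Bmex348H	40	3.774	4	0.944
B. mexicanum	Bmex504	40	3.774	4	0.944
B. phoenicoides	Bpho6-1R	28	1.443	4	0.361
B. phoenicoides	Bpho422	28	1.469	4	0.367
B. phoenicoides	Bpho452	38	2.176	6	0.363
B. phoenicoides	Bpho552	38	2.204	6	0.367
B. phoenicoides	Bpho553	38	2.183	6	0.364
B. phoenicoides	Bpho554-1	38	2.155	6	0.359
B. pinnatum	Bpin505	18	0.822	2	0.411
B. pinnatum	Bpin34	28	1.449	4	0.362
B. pinnatum	Bpin514	28	1.537	4	0.384
B. pinnatum	Bpin520	28	1.499	4	0.375
B. retusum	Bret400	32	1.704	4	0.426
B. retusum	Bret407	32	1.715	4	0.429
B. retusum	Bret453-4	32	1.840	4	0.460
B. retusum	Bret454	32	1.862	4	0.466
B. retusum	Bret504	32	1.669	4	0.417
B. retusum	Bret555	32	1.715	4	0.429
B. retusum	Bret403	42	2.373	6	0.396
B. retusum	Bret408	42	2.431	6	0.405
B. retusum	Bret551	42	2.109	6	0.352
B. retusum	Bret557	42	2.464	6	0.411
B. retusum	Bret561	42	2.362	6	0.394
B. rupestre	Brup7	28	1.562	4	0.391
B. rupestre	Brup439-1	28	1.550	4	0.388
B. rupestre	Brup441	28	1.483	4	0.371
B. rupestre	Brup442	28	1.560	4	0.39
B. rupestre	Brup443	28	1.498	4	0.375
B. rupestre	Brup444	28	1.492	4	0.373
B. rupestre	Brup182	38	2.258	6	0.376
B. rupestre	Brup600	38	2.216	6	0.369
B. rupestre	Brup605	38	2.265	6	0.378
B. sylvaticum	Bsyl54-1	18	0.888	2	0.444
B. sylvaticum	Bsyl466-6	18	0.928	2	0.464
B. sylvaticum	Bsyl477-1	18	0.932	2	0.466
B. sylvaticum	Bsyl501-6	18	0.947	2	0.474
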