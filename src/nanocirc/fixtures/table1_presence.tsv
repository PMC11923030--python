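circrna_id	accession	Caco-2	COLO 205	DLD-1	RKO	HT-29	HCT 116	SW 620
circ-BCL2L12-1	ON142203.1	-	+	+	+	-	+	-
circ-BCL2L12-2b	ON141952.1	+	-	-	-	-	-	+
circ-BCL2L12-3	ON141935.1	-	-	-	+	-	-	-
circ-BCL2L12-4	ON141936.1	-	-	-	+	-	-	-
circ-BCL2L12-5	ON141937.1	-	-	-	-	+	-	-
circ-BCL2L12-6	ON141938.1	-	-	-	-	-	+	-
circ-BCL2L12-8	ON141940.1	-	+	-	-	-	-	-
circ-BCL2L12-9	ON141941.1	-	+	-	-	-	-	-
circ-BCL2L12-10	ON141942.1	-	+	-	-	-	-	-
circ-BCL2L12-11	ON141943.1	-	-	-	+	+	-	-
circ-BCL2L12-12	ON141944.1	-	-	-	-	-	+	-
circ-BCL2L12-13	ON141945.1	+	-	-	-	-	-	-
circ-BCL2L12-14	ON141946.1	+	-	+	-	-	-	-
circ-BCL2L12-15	ON141947.1	+	-	+	-	-	-	-
circ-BCL2L12-16	ON141948.1	-	-	+	-	-	-	-
circ-BCL2L12-17	ON141949.1	-	-	+	-	-	-	-
circ-BCL2L12-18	ON141950.1	-	-	-	-	-	+	-
circ-BCL2L12-19	ON141951.1	-	-	-	+	-	-	-
circ-BCL2L12-21	ON141953.1	+	-	+	-	-	+	-
circ-BCL2L12-22	ON141954.1	+	-	-	-	-	-	-
circ-BCL2L12-23	ON141955.1	-	-	-	-	-	+	-
circ-BCL2L12-24	ON141956.1	-	-	-	-	+	-	-
circ-BCL2L12-25	ON141957.1	+	-	-	-	-	-	-
circ-BCL2L12-26	ON141958.1	-	-	-	-	-	+	-
circ-BCL2L12-27a	ON141959.1	-	-	-	-	+	-	-
circ-BCL2L12-28	ON141960.1	-	-	-	-	-	+	-
circ-BCL2L12-29	ON141961.1	-	-	-	-	-	+	-
circ-BCL2L12-30	ON141962.1	-	-	-	-	-	+	-
circ-BCL2L12-31	ON141963.1	-	+	-	-	-	+	-
circ-BCL2L12-32	ON141964.1	-	+	-	-	-	-	-
circ-BCL2L12-33	ON141965.1	-	-	+	-	-	-	+
circ-BCL2L12-34	ON141966.1	-	+	+	-	+	+	+
circ-BCL2L12-35a	ON141967.1	-	-	-	+	+	-	-
circ-BCL2L12-36	ON141968.1	+	-	-	-	-	+	+
circ-BCL2L12-37	ON141969.1	-	-	-	-	-	-	+
circ-BCL2L12-38	ON141970.1	-	-	+	-	-	-	-
circ-BCL2L12-39	ON141971.1	-	-	+	-	-	-	-
circ-BCL2L12-40	ON141972.1	-	-	-	-	+	-	-
circ-BCL2L12-41	ON141973.1	-	+	-	-	-	-	-
circ-BCL2L12-42	ON141974.1	-	-	-	-	-	+	-
circ-BCL2L12-43	ON141975.1	-	-	-	-	-	-	+
circ-BCL2L12-44	ON141976.1	-	+	-	-	-	-	-
circ-BCL2L12-46	ON141978.1	+	-	-	-	-	-	-
circ-BCL2L12-47b	ON141979.1	-	-	-	-	-	-	+
circ-BCL2L12-55	OQ317928.1	-	-	-	-	+	-	-
circ-BCL2L12-92	ON746136.1	-	-	-	-	-	+	-
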