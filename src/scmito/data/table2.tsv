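variant	in_WGS	in_WES	is_in_bulk	maf_WGS	maf_WES	maf_bulk	low_bulk_depth
m.73A>G	5	1	1	1.00	1.00	1.00	0
m.73A>T	5	1	1	1.00	1.00	1.00	0
m.114C>T	5	2	1	1.00	1.00	1.00	0
m.263A>G	6	3	1	1.00	1.00	1.00	0
m.310T>C	4	1	0	0.38	0.68	0	0
m.497C>T	5	2	1	0.99	0.99	1.00	0
m.750A>G	7	2	1	1.00	0.98	1.00	0
m.1189T>C	5	2	1	1.00	0.97	1.00	0
m.1352C>T	2	-	0	0.06	-	0	0
m.1413T>C	6	2	1	1.00	1.00	1.00	0
m.1438A>G	6	2	1	1.00	1.00	1.00	0
m.1811A>G	9	2	1	1.00	1.00	1.00	0
m.2706A>G	9	3	1	1.00	0.91	1.00	0
m.3480A>G	9	3	1	1.00	0.99	1.00	0
m.4769A>G	4	1	1	1.00	1.00	1.00	0
m.5591G>A	2	-	0	0.08	-	0	0
m.7028C>T	4	1	1	1.00	1.00	1.00	0
m.8860A>G	4	1	0	1.00	1.00	1.00	1
m.9055G>A	9	6	1	1.00	1.00	1.00	0
m.9510T>C	6	4	0	0.31	0.36	0.37	1
m.9698T>C	8	4	1	0.99	0.99	0.97	0
m.10398A>G	9	2	0	0.99	1.00	1.00	1
m.10550A>G	9	3	1	0.99	1.00	1.00	0
m.10978A>G	7	4	1	0.99	0.98	1.00	0
m.11145C>A	3	-	0	0.06	-	0	0
m.11299T>C	9	7	1	1.00	0.99	1.00	0
m.11467A>G	9	5	1	1.00	1.00	1.00	0
m.11470A>G	9	5	1	1.00	1.00	1.00	0
m.11719G>A	8	3	1	1.00	1.00	1.00	0
m.11914G>A	7	3	1	1.00	1.00	1.00	0
m.12308A>G	7	2	1	1.00	1.00	1.00	0
m.12372G>A	7	4	0	1.00	1.00	0.96	1
m.12954T>C	5	6	1	1.00	1.00	1.00	0
m.13831C>A	5	5	0	0.37	0.34	0.22	1
m.14167C>T	7	9	1	1.00	1.00	1.00	0
m.14766C>T	9	4	1	1.00	0.99	1.00	0
m.14798T>C	8	6	1	1.00	0.99	0.96	0
m.15289T>C	2	-	0	0.08	-	0	0
m.15326A>G	9	3	1	1.00	1.00	1.00	0
m.15924A>G	9	3	1	1.00	1.00	1.00	0
m.16224T>C	7	6	1	0.99	1.00	1.00	0
m.16234C>T	7	6	1	1.00	1.00	1.00	0
m.16311T>C	8	5	1	1.00	1.00	1.00	0
m.16519T>C	5	1	1	1.00	0.97	1.00	0
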