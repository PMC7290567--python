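variant	n_cells	is_in_bulk	maf	maf_bulk	low_bulk_depth
m.73A>G	43	1	1.00	1.00	0
m.150C>T	44	1	1.00	1.00	0
m.199T>C	45	1	1.00	1.00	0
m.263A>G	44	1	1.00	1.00	0
m.489T>C	47	1	1.00	0.06	0
m.750A>G	47	1	1.00	1.00	0
m.1438A>G	44	1	1.00	1.00	0
m.2706A>G	46	1	1.00	1.00	0
m.3572T>C	9	0	0.04	1.00	1
m.4048G>A	43	1	1.00	0.01	0
m.4071C>T	40	1	1.00	1.00	0
m.4164A>G	34	1	1.00	1.00	0
m.4769A>G	1	1	1.00	1.00	0
m.5351A>G	28	1	0.99	1.00	0
m.5460G>A	47	1	0.99	1.00	0
m.6455C>T	47	1	1.00	1.00	0
m.6680T>C	43	1	1.00	1.00	0
m.7028C>T	38	1	1.00	1.00	0
m.7684T>C	42	1	1.00	1.00	0
m.7853G>A	46	1	1.00	1.00	0
m.8552T>C	43	1	1.00	1.00	0
m.8563A>C	1	0	0.08	1.00	1
m.8684C>T	1	0	0.18	1.00	1
m.8701A>G	40	1	1.00	1.00	0
m.8860A>G	1	1	1.00	1.00	0
m.9540T>C	47	1	1.00	1.00	0
m.9627G>A	46	1	0.18	0.02	0
m.9824T>C	47	1	1.00	0.99	0
m.10345T>C	47	1	1.00	1.00	0
m.10398A>G	45	1	1.00	1.00	0
m.10400C>T	45	1	1.00	0.99	0
m.10873T>C	44	1	1.00	1.00	0
m.11284C>T	36	1	0.08	0.99	0
m.11719G>A	44	1	0.98	1.00	0
m.12405C>T	47	1	1.00	1.00	0
m.12705C>T	44	1	1.00	1.00	0
m.12811T>C	47	1	1.00	1.00	0
m.12906C>T	1	0	0.20	1.00	1
m.13239C>T	1	0	0.07	1.00	1
m.14766C>T	39	1	1.00	1.00	0
m.14783T>C	42	1	1.00	1.00	0
m.15043G>A	47	1	1.00	1.00	0
m.15301G>A	46	1	1.00	1.00	0
m.15326A>G	47	1	1.00	0.01	0
m.16129G>A	46	1	0.99	1.00	0
m.16189T>C	39	1	1.00	0.99	0
m.16223C>T	46	1	1.00	1.00	0
m.16297T>C	47	1	1.00	0.17	0
m.16298T>C	47	1	1.00	1.00	0
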