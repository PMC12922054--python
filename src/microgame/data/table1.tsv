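	C1	C2	C3	C4	C5	E1	E2	E3	E4	E5
gene1	4.817	4.906	4.942	4.920	4.909	4.770	5.050	4.859	4.752	5.353
gene2	4.771	4.649	4.819	4.706	4.195	4.705	4.574	4.317	4.574	4.480
gene3	3.678	3.610	3.669	3.817	3.714	3.628	3.560	3.624	3.502	3.728
gene4	2.972	3.069	3.214	3.334	3.069	3.022	3.181	3.168	3.021	3.177
gene5	3.470	3.528	3.528	3.719	3.472	3.417	3.514	3.517	3.267	3.706
gene6	4.982	5.110	5.284	5.182	5.759	4.645	5.060	5.196	4.632	5.589
gene7	4.201	3.868	4.048	3.981	3.868	3.903	3.983	3.817	3.778	3.663
gene8	3.326	3.309	3.346	3.492	3.392	3.259	3.285	3.332	3.207	3.400
gene9	6.279	6.489	6.359	6.660	6.875	6.318	6.538	6.661	6.413	6.591
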