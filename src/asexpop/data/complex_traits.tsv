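complex_id	lineage	S_total	S_prun1	S_prun2	D_total	D_prun1	D_prun2	Dratio_total	Dratio_prun1	Dratio_prun2	Dstar_total	Dstar_prun1	Dstar_prun2	age_mya_min	age_mya_max	age_is_lgm	gen_per_year	body_mass_g	body_length_mm	is_vertebrate	isolated_from_sex	is_polyploid	latitude_max	n_sexual_sampled
Schmidtea_polychroa	asexuals	40	28	15	-0.275	-2.230	-1.754	-0.044	-0.818	-0.688	-0.388	-2.390	-2.080	0.75	1.5	0	9	0.050	8	0	1	1	NA	NA
Tropidophoxinellus_alburnoides	asexuals	130	110	67	-2.014	-2.670	-2.530	-0.681	-0.910	-0.876	-3.980	-6.190	-5.250	1.8	3.6	0	1	150	250	1	0	1	NA	NA
Potamopyrgus_antipodarum	asexuals	36	29	21	-0.733	-1.560	-1.246	-0.280	-0.344	-0.231	-1.501	-2.660	-1.638	0.5	0.5	0	2	10	90	0	0	1	NA	NA
Ambystoma	asexuals	6	NA	NA	-0.629	-0.629	-1.440	-0.299	-0.299	-0.239	-0.503	-0.503	-0.380	NA	NA	1	1	15	90	1	0	1	NA	NA
Daphnia_pulex	asexuals	48	140	30	-1.878	-2.630	-2.361	-0.651	-0.900	-0.851	-3.582	-4.150	-3.480	0.172	0.172	0	10	0.002	2	0	1	0	NA	NA
Menetia_greyi	RP_parthenogens	12	12	12	1.233	1.233	1.233	0.526	0.526	0.526	0.703	0.703	0.703	NA	NA	0	NA	2	50	1	1	1	NA	NA
Menetia_greyi	WP_parthenogens	11	11	11	-2.172	-2.172	-2.172	-0.910	-0.910	-0.910	-2.827	-2.827	-2.827	NA	NA	0	NA	2	50	1	1	1	NA	NA
Campeloma_limum	asexuals	66	35	12	0.533	-1.350	-1.243	0.242	-0.493	-0.630	1.236	-1.940	-1.298	0.56	0.56	0	1	5	50	0	1	1	NA	NA
Cobitis	elongatoides_like	24	NA	13	-0.770	NA	-0.750	-0.288	NA	-0.306	-1.142	NA	-2.470	0.342	0.342	0	1	15	135	1	1	1	NA	NA
Cobitis	taenia_like	7	NA	3	-0.560	NA	-0.530	-0.254	NA	-0.300	0.630	NA	-0.190	NA	NA	1	1	15	135	1	1	1	NA	NA
Cobitis	pooled	NA	19	NA	NA	-1.090	NA	NA	-0.424	NA	NA	-2.940	NA	0.342	0.342	0	1	15	135	1	1	1	NA	NA
Phoxinus_eos_neogaeus	asexuals	5	4	4	0.062	0.263	0.263	0.031	0.129	0.149	0.980	0.886	0.886	NA	NA	1	1	10	90	1	0	1	NA	NA
Timema_poppensis	clade_4_2	9	6	2	-1.540	-1.920	-0.980	-0.670	-0.903	-0.635	-0.330	-2.360	-0.700	0.5	0.5	0	1	0.050	50	0	0	0	NA	NA
Bacillus_rossius	asexuals	10	10	6	-1.920	-1.920	-1.870	-0.829	-0.829	-0.880	-1.920	-1.920	-2.200	1.06	1.06	0	1	0.050	NA	0	0	0	NA	NA
Aspidiotus	parthenogens	24	NA	NA	-1.110	-1.060	-1.270	-0.390	-0.415	-0.455	-1.170	-1.170	-1.400	1	1	0	1	0.050	10	0	0	0	NA	NA
Poecilia_formosa	asexuals	10	10	6	-0.720	-0.720	-1.040	-0.305	-0.305	-0.500	-0.540	-0.550	-1.530	0.081	0.081	0	3	10	90	1	0	0	NA	NA
Warramaba	parthenogens	52	NA	NA	0.930	-0.360	-0.620	0.290	-0.114	-0.230	1.560	0.240	0.260	0.33	0.33	0	1	0.050	NA	0	1	0	NA	NA
Leptynia	parthenogens	15	NA	NA	0.780	-1.140	-1.400	-0.330	-0.530	-0.490	0.260	-1.020	-1.270	2.86	2.86	0	1	0.050	70	0	1	0	NA	NA
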