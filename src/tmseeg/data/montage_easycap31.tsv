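label	x	y	z3	x3	y3
Fp1	-0.347538	0.990749	-0.078359	-0.329991	0.940726
Fp2	0.348510	0.990453	-0.078426	0.330899	0.940402
F7	-0.931084	0.562845	-0.137767	-0.847627	0.512395
F3	-0.458234	0.484385	0.499834	-0.595220	0.629189
Fz	0.002452	0.459555	0.750566	0.003526	0.660786
F4	0.471587	0.494045	0.477633	0.606623	0.635512
F8	0.930257	0.565743	-0.139004	0.846108	0.514567
FC5	-0.787211	0.190070	0.294293	-0.929019	0.224309
FC1	-0.248875	0.190051	0.881445	-0.375357	0.286639
FCz	0.002619	0.190734	0.955445	0.004053	0.295142
FC2	0.256568	0.195006	0.874587	0.386023	0.293400
FC6	0.791122	0.198299	0.285628	0.929583	0.233006
TP9	-1.124058	-0.610672	-0.424683	-0.795524	-0.432188
T7	-1.050320	-0.199911	-0.108447	-0.976571	-0.185874
C3	-0.501982	-0.089337	0.696060	-0.706876	-0.125802
Cz	0.002539	-0.058055	0.995837	0.003983	-0.091066
C4	0.514622	-0.083577	0.682983	0.720988	-0.117092
T8	1.053360	-0.185964	-0.109187	0.978884	-0.172815
TP10	1.121989	-0.612488	-0.423333	0.795203	-0.434097
CP5	-0.685245	-0.400776	0.318205	-0.818335	-0.478616
CP1	-0.219706	-0.292577	0.839339	-0.326425	-0.434692
CP2	0.237405	-0.291148	0.830884	0.351645	-0.431251
CP6	0.698594	-0.386527	0.311412	0.831488	-0.460056
P7	-0.712928	-0.722951	-0.024101	-0.701950	-0.711819
P3	-0.369026	-0.548505	0.507570	-0.480960	-0.714878
Pz	0.001978	-0.494166	0.713552	0.002804	-0.700597
P4	0.382663	-0.540037	0.506513	0.498504	-0.703519
P8	0.718109	-0.718233	-0.024575	0.706832	-0.706954
O1	-0.240830	-0.920705	0.075827	-0.252329	-0.964666
O2	0.244746	-0.919817	0.075607	0.256398	-0.963610
Iz	0.000043	-1.122384	-0.191059	0.000037	-0.981579
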