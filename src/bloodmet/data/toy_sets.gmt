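TOY_TRANSPORT_A	synthetic toy set	G0001	G0002	G0003	G0004	G0005
TOY_TRANSPORT_B	synthetic toy set	G0003	G0004	G0005	G0006	G0007	G0008
TOY_IMMUNE_SIGNALING	synthetic toy set	G0009	G0010	G0011	G0012	G0013	G0014	G0015
TOY_METABOLISM	synthetic toy set	G0005	G0016	G0017	G0018	G0019
TOY_CELL_ADHESION	synthetic toy set	G0020	G0021	G0022	G0023
TOY_STRESS_RESPONSE	synthetic toy set	G0001	G0024	G0025	G0026	G0027	G0028
TOY_SECRETION	synthetic toy set	G0029	G0030	G0003	G0031
TOY_UNMEASURED	synthetic toy set	ZZZ_NOT_ON_CHIP_1	ZZZ_NOT_ON_CHIP_2
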