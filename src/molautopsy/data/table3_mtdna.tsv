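case_id	proband_all	proband_dloop	mother_all	mother_shared_all	mother_dloop	mother_shared_dloop	father_all	father_shared_all	father_dloop	father_shared_dloop
MA02010	17	5
MA00066	16	5
MA00056	15	9	15	15	9	9	6	6	4	4
MA04004	12	4
MA00025	12	7
MA00017	11	4
MA00011	11	5	11	11	5	5	0	0	0	0
MA00005	10	4	10	10	4	4	0	0	0	0
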