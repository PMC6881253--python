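protein_id	species	context_seq	motif_start	motif_end	declared_class	evidence_code	kd_molar	measure_ph	measure_temp_K	disorder_call	disorder_avg
p21	H. sapiens	RQTSMTDFYHSKRRL	2	9	pip_degron	B	8.0e-8	7.4	298.15	D	0.72
FEN1	H. sapiens	TQGRLDDFFKVTGSL	2	9	pip_box	B	4.5e-5	7.4	298.15	D	0.71
MSH6	H. sapiens	RQSTLYSFFPKSPAL	2	9	pip_box	B	2.9e-6	7.4	298.15	D	0.59
UNG2_variant	H. sapiens	MIGQKTLYSFFTPSP	4	11	pip_box	B	3.4e-5	7.4	298.15	D	0.83
Spd1	S. pombe	IQGSLMDVGMRVRKS	2	9	pip_degron	B		7.4		D	0.86
APIM_peptide	H. sapiens	MDRWLVKW	3	7	apim	B	1.1e-5	7.4	298.15	D	0.70
Srs2	S. cerevisiae	ASSQMDIF	1	8	unknown	B				F	0.22
CAF1	H. sapiens	QARL--PF	1	8	pip_box	B				D	0.88
DNA_ligase	S. solfataricus	EGKAVDLL	1	8	unknown	B				D	0.73
p21_like_designed	H. sapiens	AQTSMTDFYHSKRRA	2	9	pip_degron	B				D	0.74
APIM_variant_designed	H. sapiens	AMDRWLVKW	4	8	apim	B				D	0.87
SYN001	H. sapiens	LDSPREILLAAP	3	10	unknown	B				D	0.97
SYN002	S. cerevisiae	REGKLRGPHHIDRR	4	11	unknown	B				D	0.68
SYN003	S. pombe	ATDNGRDENGKARSE	5	12	unknown	B				D	0.61
SYN004	D. melanogaster	NQGLRGGDSQLIS	3	10	unknown	B*				D	0.58
SYN005	S. solfataricus	ERIKDKIAKIKNP	4	11	unknown	C				D	0.52
SYN006	P. furiosus	DDKIELSDHLALAK	3	10	unknown	B				D	0.85
SYN007	H. sapiens	RRRGTSSIGTTYINQ	5	12	unknown	CY				D	0.55
SYN008	H. sapiens	PLHREDHNRHFIDA	5	12	unknown	B				D	0.56
SYN009	S. cerevisiae	RGATKANHFAEP	3	10	unknown	B				F	0.21
SYN010	S. pombe	DGPRIVHLEFAS	3	10	unknown	B				F	0.08
SYN011	D. melanogaster	RVGTEEHLKTFKQT	5	12	unknown	B				D	0.94
SYN012	S. solfataricus	QPQNVLLNSFQNQTP	4	11	unknown	B*				F	0.34
SYN013	P. furiosus	HVVNSALLGHNFASK	5	12	unknown	C				D	0.66
SYN014	H. sapiens	HPKDSTVLGTYKLH	5	12	unknown	B				F	0.10
SYN015	H. sapiens	NDSNPLIRVYPNL	3	10	unknown	CY				D	0.83
SYN016	S. cerevisiae	DTLKSSLINKAYLVTI	5	12	unknown	B				D	0.71
SYN017	S. pombe	VAATSNLDGYKGHE	4	11	unknown	B				D	0.63
SYN018	D. melanogaster	IEEPSKIIVIYGNSR	4	11	unknown	B				D	0.91
SYN019	S. solfataricus	ETEETQLILLNFSGAH	5	12	unknown	B				D	0.81
SYN020	P. furiosus	AQISDHIDEVYDG	4	11	unknown	B*				F	0.50
SYN021	H. sapiens	NSKQHSILDYNQI	4	11	unknown	C				D	0.51
SYN022	H. sapiens	LTGQRSIEHYQSAD	4	11	unknown	B				F	0.47
SYN023	S. cerevisiae	SRKDQRRLHELFSE	5	12	unknown	CY				D	0.84
SYN024	S. pombe	VIQQVMHIYQLLK	3	10	unknown	B				D	0.77
SYN025	D. melanogaster	VRTQDPMLEIYNGL	4	11	unknown	B				D	0.55
SYN026	S. solfataricus	RQHKQTHLRQHFDS	5	12	unknown	B				D	0.87
SYN027	P. furiosus	AHQDQQGMTRHFDELG	5	12	unknown	B				F	0.44
SYN028	H. sapiens	HLQTEILPEYNT	3	10	unknown	B*				D	0.80
SYN029	H. sapiens	ANSRQTEMKTFANNS	5	12	unknown	C				D	0.87
SYN030	S. cerevisiae	VHPVQKVLELYLEVE	5	12	unknown	B				D	0.97
SYN031	S. pombe	HHEAQDKIHPYGKT	5	12	unknown	CY				F	0.32
SYN032	D. melanogaster	NVQHLILDYLVR	3	10	unknown	B				F	0.50
SYN033	S. solfataricus	NAQVNMEISFPGL	3	10	unknown	B				F	0.06
SYN034	P. furiosus	SRKGQNTLSIHYREQE	5	12	unknown	B				F	0.31
SYN035	H. sapiens	RHNQQQLTAYHRR	4	11	unknown	B				F	0.41
SYN036	H. sapiens	VEQEEVKHFAAD	3	10	unknown	B*				F	0.00
SYN037	S. cerevisiae	HLEQSPITRKYRNP	4	11	unknown	C				D	0.94
SYN038	S. pombe	GPAQQTGLDEFQRNI	5	12	unknown	B				D	0.84
SYN039	D. melanogaster	LDQGRISKYYKRHD	3	10	unknown	CY				D	0.85
SYN040	S. solfataricus	DEQEQVRKFFELH	3	10	unknown	B				D	0.56
SYN041	P. furiosus	IAVQTVESVYFDP	4	11	unknown	B				D	0.62
SYN042	H. sapiens	KTQKPTSHFFSAKL	3	10	unknown	B				F	0.36
SYN043	H. sapiens	RHAQPKLQPFYVII	4	11	unknown	B				F	0.36
SYN044	S. cerevisiae	PDSQQILLNHYFTV	5	12	unknown	B*				D	0.88
SYN045	S. pombe	RLQDQLGDFFTRNP	3	10	unknown	C				F	0.14
SYN046	D. melanogaster	KHRQPHLEPFFRISG	4	11	unknown	B				D	1.00
SYN047	S. solfataricus	RIQRQVPKYYIPHP	3	10	unknown	CY				D	0.90
SYN048	P. furiosus	RQVHQSRVSGYYKVE	5	12	unknown	B				D	0.64
SYN049	H. sapiens	LDLIQRVILVYYNLT	5	12	unknown	B				D	0.72
SYN050	H. sapiens	NSQQIVHGYYKT	3	10	unknown	B				D	0.82
SYN051	S. cerevisiae	SIIQSTLAVYYKHAG	4	11	unknown	B				F	0.22
SYN052	S. pombe	NHQTQLRLHRFFLKIN	5	12	unknown	B*				D	0.76
SYN053	D. melanogaster	RPQLLVERFFQHI	3	10	unknown	C				F	0.05
SYN054	S. solfataricus	IPQSEIHVYFTNT	3	10	unknown	B				D	0.52
SYN055	P. furiosus	SNQTNVNVFYRANK	3	10	unknown	CY				D	0.84
SYN056	H. sapiens	AKQQIILGYYEE	3	10	unknown	B				D	0.72
SYN057	H. sapiens	IKQGQIQMPNYFIE	5	12	unknown	B				F	0.17
SYN058	S. cerevisiae	VIGQNIMRLYYRN	4	11	unknown	B				D	0.90
SYN059	S. pombe	RTEQAVIRKYFLQLT	4	11	unknown	B				F	0.47
SYN060	D. melanogaster	SVPQNLIIDFFTQST	4	11	unknown	B*				D	0.94
SYN061	S. solfataricus	QGNRQVELTSYFGE	5	12	unknown	C				F	0.14
SYN062	P. furiosus	GNHQNSMNGFYERK	4	11	unknown	B				D	0.54
SYN063	H. sapiens	TKHQIPMQEYFVSHK	4	11	unknown	CY				D	0.91
SYN064	H. sapiens	EDRQGRVEQFFAD	4	11	unknown	B				D	0.80
SYN065	S. cerevisiae	VQVQQGDLNQFYVLH	5	12	unknown	B				D	0.95
SYN066	S. pombe	PKKRQSAIQDFYIRRI	5	12	unknown	B				F	0.26
SYN067	D. melanogaster	ANDDQTQLVRFFAIH	5	12	unknown	B				F	0.29
SYN068	S. solfataricus	KLEQVILVEFFSQV	4	11	unknown	B*				F	0.42
SYN069	P. furiosus	KVRATHSLRGFFLKVP	5	12	unknown	C				D	0.74
SYN070	H. sapiens	VSAPGMAQYFHGQ	3	10	unknown	B				D	0.98
SYN071	H. sapiens	SVAGDSLKDFFVPT	4	11	unknown	CY				F	0.13
SYN072	S. cerevisiae	NQNAGGEVELYFGNGK	5	12	unknown	B				D	0.96
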