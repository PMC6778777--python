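individual	barcode	sex	filtered_reads	ustacks_loci	mean_depth
C38AF	ACTGG	female	10897888	387597	27.51
C39AF	ACTTC	female	8453283	364016	22.69
C91CF	ATACG	female	9888747	362344	26.73
C92DF	ATGAG	female	1671803	147468	10.94
C93DF	ATTAC	female	2609406	194087	13.03
C100EF	CATAT	female	5058754	283782	17.39
C104EF	CGAAT	female	3495437	229634	14.82
C109EF	CGGTA	female	4170971	257133	15.81
C110EF	CGTAC	female	7084986	324687	21.34
C31AM	GCATG	male	8668485	366678	22.46
C32AM	AACCA	male	3243953	260992	11.47
C33AM	CGATC	male	2980522	251412	10.93
C34AM	TCGAT	male	5346185	311318	16.22
C35AM	TGCAT	male	4507062	290538	14.65
C36AM	CAACC	male	7184657	350200	19.35
C89CM	GGTTG	male	5613817	321310	16.45
C94DM	AAGGA	male	8934375	351762	24.31
C97DM	AGCTA	male	4946750	315847	14.62
C101EM	ACACA	male	5932130	322649	17.38
C108EM	CGGCT	male	3146455	216458	14.13
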