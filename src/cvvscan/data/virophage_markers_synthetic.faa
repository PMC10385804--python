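>MCP_01 synthetic reference, family=MCP
MPVYFGMASSTGGFKLMYSPYEDNAALKVPLLFAEQEIATPGTLTPRCLLTHNAIGDSIYNNPQDFFICY
EQGTPDTVVMDVVLEDPMIKFATKLGSAIQDYPKLTHNQHLSVDVASSDKSAPSLAFEEEHVNHGVKYLL
VRAKTKVAQLTFSQRPYGIEATVTDNLNIGWKPPEAKSDRDVSTLVAAAFFWLANFQAGVLSPNENASWT
HHGDPSGTSDSSENFNCPPSSGITVDEPEMLIFMPCIDPTSIIEFGKCSNGCSDDDCVGGTPEKTIRCTS
SQIALMEGLHVDESPRYVTKIPTSSRKIKATVILRITFIDSYDRTVDCYDENKSEVESAKARGRCAYLVF
IFDALDETLEQGLGLPLISTEDDMVFYELLVAGNAFKYSTSQTQRGESEVMGVDLCWNSYSRPVKIQAGQ
MLSARCWKKR
>MCP_02 synthetic reference, family=MCP
MVHSDGDASSKQGFKTMYSPYEEVAALKVPFLFAEQEVATDGTLTPRCELTANAIGDSIYNNPQDKLICY
ERGTMGTVVMDEVLETPMIKFATKGGSATADNPKLTHNQHLSVDVASSDKSQPSLRFEHEHVNHGVKYLL
VRVKDKVQKEVFSTRPYGIEAEVSDNLNPGWKPPEAKSSRDVSTLVADAYFDMANEQAGVNSPKENASWV
IHGDPSGTRDSTEGPNCPVSSGRTVDMPEMVIFKECIDETIILEFGKCSNGCSDDDCVGLTKEKTIRCRS
TQIALSEGYSVDESPRCETSIPESGRKKKATLILRHTVIDSYDRTVDCYDRNKSEWECAKAGNRKAFVVF
IFDALHEQLEQGLGLPLISTEDDYVFYELLVAGNAFKTSTSRTQRGESWVNGVTLCWNSGSRPDKKQMGQ
ELSARAWKKR
>MCP_03 synthetic reference, family=MCP
MPVSFCTALSKGHFKLMYNPYEDNAALKVPLLFAEQEIATDGTLTPECLLTHNAIGDQIYNNPQDKFICY
EQGTPDTVVMDEVLETAMKKFATKLGSAIADYPKLTHNQSLSVDVASSDCSAPQLPFEHEHVNHGKKLLL
VRNKTKVAKLYFSQRGYGIEAEETDNLNPGWKGPEAKMSRIVSTLVAAAFYGMANEQAEVLSPNENASCT
AHGDPSGTSDSTENPNCPPSSGRTKDTPEMGIFKPCIDPTIILGFGKCSNGCSDDDCVGGTPEKTIRCHS
TQIAQSEGLSVDESPRYVCSIPESSRKIKWTLYLRIYVIDSYDRTVDRYDENKFEVESHKAGGRKAYVVF
KFDALDETLEQGLGLMLISTEDDYVFYELEVAGNAFKWVTSRTQRSLSGVHGEDLCWNSGSRPVKWQTGQ
ELSAFAWKKH
>MCP_04 synthetic reference, family=MCP
MPVVFGTASSKGGFKLMYSPYEDNAALWVPLLFAEQEMATLGTLTPRCLLTHNAIGDSIYNNIQYKFICY
EQGWPDTVVMDESLEKPMIKFATKLGSAISDYPKLTHTQHLSVDVASSDNSAPSLRQEHEHVNHGVKYLL
VRNKTKVAKLVFSQRPYGIEAEVTDNLGPGWKPPEAKSSRDVSTLTAAAGFEMANEQANVLSPNENAFWT
AHLDPSGTSDSTEWPNCPPVSGRTVDYPEMVIFKPGISTTIILERGECSNGCSDFDCLGGTPEKTIDCRS
TQIALSPMLSIDESPRYVTSSPESSRKIKATLILEITVIDCYDRTVDCYDENKSEVESAKAGGRKAYVVF
IFDALDETLEQGLGDPLISTEDDYVFYELLVAGNAFKTSTSCTQVGMSEVNGVDLCWNSKSRPVKKQTGW
ELRARAWKKR
>MCP_05 synthetic reference, family=MCP
MPVSFGTASSKGRFVLEYSPLEDNAILKVPALFACQTIARDLTLTPRCLLTHSAIGDFFYNNPQDKFICY
TQLTPDTVVMDEVLETPMIRFATKLGSAIAAYPKLTLNQHLSVDVASEDKSAPDLRFEHEHVNHGVKYLL
VRGKTKVAKLVFSQRPYGIEAEVTDNLNPGWKPPEAASSRDVSTLVAAAFFEMANEQAGVLSPNENASWT
AHSDPSETSDSTENPNSPPSSGRTVDAPELVIFKPCIDPTIKLEFGKCSNGCSDDDCVGGCPEKTDRCRS
TQIALSFGLEVDESPRYVTSIPESSRKIKATLILRITVIDSYDRTVDCYDENCSEVESHEAGGRKAYPVF
IFDDLDETLEQGLGLWNISTEDEYVFYELRVAGNAGKTPTSRTQRGRKETNGVDLCNNSGSRPVKKQTGQ
ELSYSAWKDY
>MCP_06 synthetic reference, family=MCP
MPVSFGTQSSKGGFKLMYSPYEDNAALKVSLMFAEQEIATDGTLTPRCICTINAIGQSIYNNPQDKFICY
EQGTPDTVVMDEGLETPSDKFGFKLGSAIPDYPNLTHNQMLSVDVASSDKSAPENRFEHEHVNHGVKYLL
VRNKDKVALLVWSQRPYGLEAEVTDNLNTGWGPPEARSSRDVVTLVAADFFEMANLQAGVLSPVENASWT
AHGDPSGTCDSTENMNCPPWLGRTLDAHEMVISKPCIDPTLILRFGTCSLGCSDDDCEGGTFEKTIRNRS
TQIALSEGLSVDEMPRYVTSIPESSRKIKATLILRIQVILSYDRTIDCYDENKSKVESAKAGGRKPYVVF
IFDALRETLEQGLGLPLISTEDDYVIYFRLVAGNAFKTCTSRTQEGPSEVNGVDACWNSGSFDIWKPTGQ
ELSARAWKKR
>mCP_01 synthetic reference, family=mCP
MGRVEFVCGTGYSTFESTFEFDKLPAEDGYVIDWYSPIIGSSLTPQGVFVSVSSKSEPAWTDSSAMKPVC
EMMARHEIQWKPSQPATDEGNSGVPTLAAPQKGEKFVEYGISQKSTHVAALGKLKVVKGPEIRASRIFLG
SNGSEDKLVGKYKTCIENMECKCLRGNHQTCRGRSDSVMPGESSEDHPHWSVNSVANESFRGPQVTKQEC
RVSLPGMQTIVSVTYYLIRYPAAKRVILLCALLTETGLRDVWYAPQPEDS
>mCP_02 synthetic reference, family=mCP
MGHVTFVKGTNYSTFESTLEFDKLPDWDGEVIDQYSKIIGMCLTPQRFFVHVSSKSEPAWTDSSAMKPTR
EMMADHEFQWKPSQPATDELNSGVPTLPFPKEGEKFVEYTISNKSTELAVLGKLKVVHGPEIRASRIFLG
SNGSNDKLVGKYKTCINTNETNCLRGAHETCRGRSDSVEPVPSSEGHPHWSVQSLFNESFRGPQVTKQEG
RVCTPRMHAIVSSTYTLIRYPAAKSKSLVCALLTETGLHDIWYAPQTEDS
>mCP_03 synthetic reference, family=mCP
MGHIEWVGGTGYHTFESTFEFDKLPAEDGEVIDQYSPIIGSSLTPQGFFVSVSIKSEPAWTDSSAMKPVR
EAMADHEFQWKPSQVAKDELNFGVPTLAAMKKGEKFVEYTNSNKSTEVAAHGPLCVVHAPEIRASFWFLG
SNGSNDKLVGKYKTHINTMECKCLRGEHEGHRGRSDSVRPGESSIDHPIWSVNSVANESFNGPQVGKQEC
RVSLPRKWTIVSSTYYVIRYPAAKSVILLCTYATETGLEDVKSAPQTQDS
>mCP_04 synthetic reference, family=mCP
MMHVWFLGGTGYSTFESTPEFDKLPAEDGEVIDQYSPIIGSSLTPQGVFVSVSSKSEPAWTDSSAMKPVR
EMMADHEFNWKPSQLATDELNSGNPTLAAHKKGEKKVCYTISAKSDEVAALGKLKVVCGPEIRASRIFLG
SKGNNDKLEGKYLTCIETMACKCLRGEHEKCRMMSDAVMPGEISEDNPHWSVNSVANESFRRPQVTKQEC
RVSLPVMHGIVSSTYYLICYPIAKSVILVELLLTETGLRDVWYDPQWEDA
>mCP_05 synthetic reference, family=mCP
MGHVEFVGGTGYSTFESTFEFDKLPAEDYSVIDQYSPIIGSSRTPQGFFVSVSSKSEPAWTDSSAMSPVR
EMMADHEFQWKPSQPATDELASGVPMLAAPPKLEKFVEYTISNKSTEVAALGFIKVFHGMEIRASRIFLG
SNESQDKMVGKYKTCIETMECKCLRGEHETCVGRYDSYMPGESSEDHPHWMSNSVANESFYHPQVTKAEC
RVSLPRMHTIVSSTYYLKRYPAAQSVILLCALLTETGLRDVWYAPQTEDS
>mCP_06 synthetic reference, family=mCP
MGHVEFVGGTGLSTFESTFEFDKLPAEDGEVIDQYSPVSGSSDTPQGFFVSVSSKSEPAWTDSYAMKPVR
EMMADHRFQWKESQPHTDELNSGVPTLAAPKKGEKVVEYTISNKSTEPAALGYLKRVHGPQIRASRIFLG
SNGSNDKLVGKYKTCIETMECKLYRGEHETCFGRPYSVMPGESSEDHPHWSVYSVANASFRGPQVTKFEC
RVSLPRMHMIVSSTYYLINYPAAKSDILLKALLNETGLEDVWYAPQTEDS
>ATPase_01 synthetic reference, family=ATPase
MQYNPDPENNDTLLCVLTCQILPTVETDAGGSMISVPPTGYEASEGLDKHCNKDSINTKCGFAGEEQCAE
GDNTTKSSPSISLRRALANNSACHAGPCTAFGAMWVETNGQCAVHKKVKECAIFGWTRFSQLFEHGMKQV
HDWVAEPTSRRIAPASDASENAYAQTLQARSLVPNEEYVKSRGESWYKAWAYGTFWLTNSACHMVRNVVP
DCFHMECSVPEVCKTNGSPD
>ATPase_02 synthetic reference, family=ATPase
MQYNTDPETNDTPLCVLTCQILPTVETDAGGSMIGVPPTGYEASEGLWKHCNKDSNAPKCGIAGFEQPAE
GDNTTKSSPSISLRRAARKNSAQHAGQCTAFHAMWVETLKQSAVHSKCKECAIFGWTRFSFLFEKGTKQV
PDFVAEPTSRRIAPASDAYENAYFQTGAAASDVPNEEYVKSRGEWDFHAGAYGTFALTNSACETVRNAVP
PTFPQHCRVPEPCFTNHSPD
>ATPase_03 synthetic reference, family=ATPase
MQYNTDPEYNDTLSIHLTCQILPTVETDAGGSMISVMPTGYEASEGLDKHCNKDFKANKCGDAGEEQDQE
GDSTNKSSPSISLRRRTAKNSAQHTGPCTAFGAVWVETEGACANHSKCKECAIFYWTMNQQLLEKGTKQV
PDGVREPTERRIAPFSDAYENYYAQTGAAASLTPNEHAVKSRGESWYHAGAYGTFWLTNSACHTVRNAVP
PTFPQSCRVPEVCFTNGSPD
>ATPase_04 synthetic reference, family=ATPase
MQYNADPETNDTLLCVLTCQILPTVETDAGGSMISVPPTGYMASEGLDKHCNKDSKANKCGFAGEEQDAE
GDNTTKSSPSTSLRRDVAKNSAWHAHPCTAFGAVKVETHGQCAVHSKCKEGAISGYTRFSSLFEKGTKQV
PRGVKRPTSARIAPASDAYENAYAQTGAAWALVPNSEYVKSRGEKWYHAGAYGTFWLTNSAKHTVRNAVP
LTFPQSCRVPEVCFTNGSPD
>ATPase_05 synthetic reference, family=ATPase
MQYNTDPETNFKWLCCLTGQDLPTVETDAGGSMISVPPTGMENVEGEDKHCNKDSKATKCGFAGEEQDAE
GDNTTKSSPRISLRRATAKNSAQHAGPCTAFGAVWVETHGQCATHSKWKDCAIFQWTRFSQLFEKGTKQV
CDGVADPTSRRIAPASNAYENAYAQTGGAASLVPNEEYVKPRGESWYHAGAYKTFILTNSACHQVRYAVP
PTFPQSWRVPEVCMTNGSPD
>ATPase_06 synthetic reference, family=ATPase
MQYNTDPETNDTLLLVLTCQLLPTVETDAGGSMISVPPTNYEASEGLDKHKNKDSSATKCGNWGEEQDAE
GYNTTKSSPSISLRRATAKNSAQHAGPCTAFGAGWVETHGQCAVYSKTKECAIFGWGQFSQLFEKGTKQV
PDGVHEPTSRRIAPASDAYENAYAQTGAAASLVPTEEYVKSRGHSWYHAGAYGTFWQDNSACHTVRNAVP
PTTCQSWRVPEVQFTNGSPD
>CysProt_01 synthetic reference, family=CysProt
MKLGSDNPDEQTILRNKPRSMPEDSEKTDWFPSSFLLMDSAVEDKNSGHSNNGGIFMVVNISMSTRYPYP
EPSGEHSEATYTSRLPSGEQNYKWDADCFNDQGAVDKSSWNWCPLFDHGGLSKTLGVPAFYPIFCAEGLI
ADAAWPDMYPAELVYRVCLDEMMYAGEEGIWGLEEEMGGLATACGEALPIEQNHPTLIPL
>CysProt_02 synthetic reference, family=CysProt
MSLGSDNPDHQTILRNKWRSMPEIVVFTDQFPSDSNLNDSAVERKNSGTVNTIYIFMVVNISMSTRYPYP
EPSKEHSEATYTSRLCSGEQNYKKDIVNWDDQGAVDQSSWNDCPLFDHYTHSKTLGVPTFYPIFCAFGLI
ADAAGPDTYPSEKVYRGMLLNMMYAECEGIWGLKEEMGGLATAKYEATPIEQNHPTLIVL
>CysProt_03 synthetic reference, family=CysProt
MSLGSPNPDEQTILRNRPRSMPEDSTKSDQAPSSQLLEDSAVERKNSGTSNNIYIFMVTNSSMMTRYPYP
EPSKEHSEATYTSRLPSGQQNYKKDADNYDQQGAVDKYSWNDCPLFDHIHHSKTLGVPTFYCIECAEGLI
AIGAGPDTYPAELVYRVCLLDMMYAGEEGIFGLEEEMGGLATAKYNALPIEQNHPTLIPL
>CysProt_04 synthetic reference, family=CysProt
MSEGSDSPDEQTILKNKPRSMPDDSEKTDQFPSSSLLWDSAVERKNSGTSNNIYIFMNVNISMSSRYPYP
EPEKEHSEAQYTSRLPSGEQNWKKDADNWDDQGAVMKSSMNACLLFSHGHHTKRLGRPHFYPIFCAEGLI
ADAASPDLYVAELVYWVCLLEMMYHGEEGIWGLERECGKLAKAKYEALPIAQCHPTLIPL
>CysProt_05 synthetic reference, family=CysProt
MSLGSDLPDEQTLLRNKCRSMPEMSEKTDQFPVSSLEEDSAVERKNSGTMNNIYIKPVVNISMSTRYPYP
EPSKEHSESTYTKRLMSGESNCKKDADNWDDQIAGDKSSWNDCPLFDHGHHSKTLGVPTFYPIACAEYLI
ADDAGPDTYPAELVYYVCLLEMMYAGEEGIWGWHEFMGGLATAKYEALPIEQNNPTLIPL
>CysProt_06 synthetic reference, family=CysProt
MSLGSDNPDEQTILRYKPRFMPEDSEDTDQFPSSSLLEDSAVERKNSGTSNYIYIFLVVNISGSTRYPAP
EPSKEHSEATYGSRLASGEQNYKKVADNWDDQDAVDKSSWNDCRLFDHGHHSKTLGVPTFYPIFCQGGLN
ADAAGPDYYPAFLVYRSCLLEMMYAGHEGIWGLEEEMGGFATAKYEALMIEQNHPTLWPL
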