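>TRAV13-2 alpha synthetic
PFATSDLGR.LTHPKIVASSITCAKDRWP.......EAFWWKSEVEATGTSYQRDAE......DYRIINSDA.ISSFAEV...RPHLIRQHGSGLPLEQLRGPC
>TRAV38-2 alpha synthetic
PEATTDPGR.QYNSKIVAVTYTCTKDRWA......QSQLWWKLEVNATEMAYQNRAY......DYPIANEDF.NSSFFLV...RPSLIKQHKSELLLLQLTVPC
>TRAV23 alpha synthetic
PFATMDPGR.LNKPKDVAMLYTCLKDVWG......QSQRWWKLEVEATLIELFRDAY......SYRMLNSDA.ISFFFEV...RPQLISQHKLKLDLEQLQVPC
>TRAV29 alpha synthetic
PYATMEPGR.LYHVKIVVMLGTCLRDKWAP.....QSQFWWAACVENAGIAYFRVAY......DYRIANSKA.ISSFKEP...LPQLIRQHKSGLDLEQLYVAC
>TRAV24 alpha synthetic
PFPTSSPGR.LKHPKLVAKLYTCLKDRWAP.....QSQFWWILEGEATEIAYFNDAY......DYRIVNSDA.ISSFFEV...RPQLIRQRKSGLVLIQLTVPC
>TRAV12-3 alpha synthetic
PFATSDLGR.LTHPKIVASSITCAKDRWP......PEAKWWKSETEATGTSYQRDAA......DYRIINSDA.ISSLAEV...RPHAIRRRGSGLPLEQLRGPC
>TRAV13-1 alpha synthetic
PEATSDLGR.LTIPKIVASSITCAKDRWPP.....QEAFWWKSEVEATHTSCQRDAE......DYRIINSDA.ISSSAEV...RPHLIRSHGSGLPLEQLRGPC
>TRAV25 alpha synthetic
CFATMDPSR.LYHPKIVAIEYTCLKDRRAP.....QSVKWWKLEVEATGIAYFRDAYY....TDYRLANTTA.ISSSGEV...RPKMIRQHQKDLDLEQLYVPC
>TRAV20 alpha synthetic
PFATMDPGR.GVHPKLVAMLIQCLDDRWA......QSDFWWKLEVEATQIAYFRDAE......IYRIATSDA.ISSFQEV...RPQPIRQHKSGLGLAQKAVPC
>TRBV7-8 beta synthetic
QVPNFLWNRYQLAPESLLEFGSCKVVKAAV.....RKQTQWKQPPNTGQWTVISQLP......AKEYDIIPW.KVAQKDI....FVAGRTSTAHSEESSVQGFC
>TRBV7-3 beta synthetic
QVPNFVWNSNQLAPKRLLLHPVCPRVWAS......RTHTQWSRNPGTGQAKFLSQLDA.....EKKYDTIPW.GVAQKDI....SAAPRTGTAHTADSSVQGFC
>TRBV7-9 beta synthetic
QVPNFVWNSNQLKPKRLLLHPFCPRVWASG.....RTHTQWSRNPGTGQAKFFSQLDA....KEKKYDYIPW.GVVQKDI....AAAPQTGTAHTADSSVQGFC
>TRBV2 beta synthetic
IVPNIQWNPVQLASSSLLEFGVCPQVGTAV.....RTHTQWSVPPGTGQWKFLSQLD......EKEHDIRPW.KVAQKDI....TPAQRWDTRYSEDSSVQVVC
>TRBV6-5 beta synthetic
QVPNEQWNPVQLASPSLLEFAVCPRVWARV.....STHTQWSVPPGTFDLKNLSQLDT.....FKEYDKIPP.KVAVKTE....TIAGRTGTAHSEDSDVQGFC
>TRBV20-1 beta synthetic
QVPNFQKNPVQLASSVLLEFGVCPGVMAA......DKHTQWSVLPGTGQIKFLSQDDA.....EKEYMIIPK.KVAQKII....RPAARTGTAHSMDSSVGGGC
>TRBV18 beta synthetic
LVPNFLWNPVQLASLSHLEFGVCKRVWADS.....RTHTRWSVPPGTLQWKFLSQVDA....KEKIYDIIPE.EVITKDI....TPMGRTGTAHSEDSSVHGFC
>TRBV5-1 beta synthetic
QVHNFQWNPVQLASCSLLGFGKCPRVWAA.......THDQWSSPPGMPQTKFLMELD......EKEYDIYPW.KVATADI....TPAGRTGTSHSELSSSQRFC
>TRBV9 beta synthetic
QVPNFAWMPAQGLASSLLEFGVCPRVWAA.......THTQWSVHPQTAQWKFDSLLDA.....EIEYDIGPW.KVAQKDI....TPAIRPGTAHVEDSSVQDFC
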