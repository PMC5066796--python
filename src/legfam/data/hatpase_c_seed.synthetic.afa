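>HATPase_c_seed_01 synthetic seed alignment row
ETFAFNADIRQLMSL-IINTVYSNKEIFLRELISNAS-DALDKLRYESLTDPSKLDSGKDLEI-RIIPDKTNN
>HATPase_c_seed_02 synthetic seed alignment row
NTFAQNAGI-QSMSK-IINNVYCNKE-FLSELIPNAV-DALGKLLYESFTDLSKLWSGEDLEA-RIFPDKKNN
>HATPase_c_seed_03 synthetic seed alignment row
EDFAFFADPRQLGSL-GINTGYSTKEITLRGLISDAS-VALDFLRLESLHDPGKLDDGKWLEIVIIIVDKTMN
>HATPase_c_seed_04 synthetic seed alignment row
ETLAFNMDIYQLMCLMIENTVNSNNEIFEREIISNPSDDQLDKARYHSLTRPSALDSRKDAEI-RMIPLKTNW
>HATPase_c_seed_05 synthetic seed alignment row
NTFEFNAGIRTLMSK-IISTVYCNKRIFLSELKSNAV-DAVDKLLYERLTDLS-PDSGEDLDI-RIFPDDTNN
>HATPase_c_seed_06 synthetic seed alignment row
EDFAQNADPRQSMSL-GINNVYSTKEQFLRGLIPNAS-VALGKLRLESFTDPGKLWSGKWLEA-RIIVDKKNN
>HATPase_c_seed_07 synthetic seed alignment row
ETLAFFADIYQLGSL--ENTGYSNNEITLREIISDAS-DQLDFLRYHSLHDPSALDDGKDAEI-IIIPLKTMN
>HATPase_c_seed_08 synthetic seed alignment row
ETFEFNMDIRTLMCLVIISTVNSNKRIFERELKSNPSHDAVDKARYERLTRPSKPDSRKDLDIYRMIPDDTNW
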