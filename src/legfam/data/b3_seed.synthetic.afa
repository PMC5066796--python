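>B3_seed_01 synthetic seed alignment row
RFFKVLLPGDVS-DRMRIPPAFARHLDGRLPE-RVTLRGPSGAEWPVELTERDGGHVYLQRGW
>B3_seed_02 synthetic seed alignment row
PFFKILLEGDVPMDRTRIPSAFNRHLPGRAPEKRATLVGPSRAEIPVEHTEMD-GHDYLCRG-
>B3_seed_03 synthetic seed alignment row
RWFKVVLPVDVS-SRMLIPPNFALHLDNRLKE-RVWLRLPSGGEWWVELSERQ-GHVELQKGW
>B3_seed_04 synthetic seed alignment row
RFMKVLSPGTVSWDVMRFPPAEARILDGPLPH-RVTWRGCSGALWPQELTIRD-LHVYWQRSW
>B3_seed_05 synthetic seed alignment row
PFFYVLLEGDCS-DRTRIDPAFNRHNDGRAPE-MVTLVGPQGAEIP-ALTEMDKGDVYLCRGG
>B3_seed_06 synthetic seed alignment row
RWFKILLPVDVP-DRMLIPSAFALHLPGRLKE-RATLRLPSRAEWWVEHTER--GHDYLQKGW
>B3_seed_07 synthetic seed alignment row
RFMKVVLPGTVS-SRMRFPPNFARILDNRLPHRRVWLRGCSGGEWPQELSERD-LHVELQRSW
>B3_seed_08 synthetic seed alignment row
RFFYVLSPGDCS-DVMRIDPAEARHNDGPLPE-MVTWRGPQGALWPVALTIRD-GDV-WQRGG
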