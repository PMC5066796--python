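>HSP90_seed_01 synthetic seed alignment row
KVIVTDRIVDSPCCLVTGEY-GWTANMERIMKAQALRDTSTMGYMASAKKHLEINPDHPIVKELRERVEADE-NDKAVKDLVL
>HSP90_seed_02 synthetic seed alignment row
TVIVWDRRVDSDCCYVTGQYYGKTANLERMMKASALCDTSAMGKMA-ATKHPEINHDHVIVKHLRHRVEKDETHDKACKDPVL
>HSP90_seed_03 synthetic seed alignment row
KNIVTPRIGDSPNCLWTGEH-GWMANMLRIHKAQSLRKTSTTGYHA-AKEHLLINPAHPEVKEEREWVEAEE-NFKAVVDLEL
>HSP90_seed_04 synthetic seed alignment row
KVVV-DWIVTSPCYLVLGEY-DWTWNMEMIMMAQAERDVSTMQYMC-AKKPLELNPDAPISKELQERSEADL-NDSAVKHLVS
>HSP90_seed_05 synthetic seed alignment row
TVIITDRRVDCPCCYVTCEY-GKTAGMERMMKPQALCDTETMGKMA-PKKHPEISPDHVIVGELRHRVPADE-HDKHVKDPVL
>HSP90_seed_06 synthetic seed alignment row
KNIVWDRIGDSDCCLWTGQYAGWMANLERIHKASALRKTSAMGYHAGATKHLLINHDHPEVKHLREWVEKDE-NFKACKDLEL
>HSP90_seed_07 synthetic seed alignment row
KVVVTPRIVTSPNCLVLGEH-GWTWNMLRIMMAQSLRDVSTTGYMC-AKEHLELNPAHPISKEERERSEAEE-NDSAVVDLVS
>HSP90_seed_08 synthetic seed alignment row
KVIITDWIVDCPCYLVTCEY-DWTAGMEMIMKPQAERDTETMQYMA-PK-PLE-SPDAPIVGELQERVPA-LENDKHVKHLVL
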