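>AP2_seed_01 synthetic seed alignment row
KYRGVRQRPW-GKWAAEIRDPKKAAR-VWLGTFDTAEAAARAYDEAALRFKGHNKAKLNFP
>AP2_seed_02 synthetic seed alignment row
HYRGFRQSPW-GWWAMEIRNPKEAAR-QWLLTFDYAEDAARRYDMAALMFKN-NKAILNAP
>AP2_seed_03 synthetic seed alignment row
KTRGVQQRWW-GKGAAFIRDIKKIARMVSLGRFDTPEAYARAEDEKALRAKG-QKAKVNFH
>AP2_seed_04 synthetic seed alignment row
KYHGVRERPF-GKWSAEHRDPRKALR-VWVGTSDTATAAWRA-AEAGLRFYG-NAAKLGFP
>AP2_seed_05 synthetic seed alignment row
HYRHVRQSPWQFKWAMEIHDPKEAAF-VWLLTFGTAEDAAVAYDMAAGRFKNHNKKKLNAP
>AP2_seed_06 synthetic seed alignment row
KTRGFRQRWW-GWWAAFIRNPKKIAR-QWLGRFDYAEAYARRYDEKAL-FKG-QKAILNFH
>AP2_seed_07 synthetic seed alignment row
KYHGVQQRPFEGKGAAEHRDIKKALR-VSLGTSDTPEAAWRAEDEAGLRAKG-NAAKVNFP
>AP2_seed_08 synthetic seed alignment row
KYRHVRERPW-FKWSAEIHDPRKAAFVVWVGTFGTATAAAVAYAE-AGRFYG-NKKKLGFP
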