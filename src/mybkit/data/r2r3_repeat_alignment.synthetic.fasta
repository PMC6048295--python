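>r2r3_consensus
LKKGPWTPEEDEILVDYIKKHGHGNWRALPKKAGLLRCGKSCRLRWTNYLRP
>r2r3_variant_01
LKKGPWTPDEDDILVDYIKKHSHGQWRALSKKASLLRCGKSARMRWTNYLRP
>r2r3_variant_02
LKKSAWTPEEDEILVDYLKKHGHGQWRALPKKAGLLRCGKSCRIRWTNHLRP
>r2r3_variant_03
MKRSAWTSEEDELILDYIKKHGHGNWRALPKKASLLRCGKTCRLRWTNFLRP
>r2r3_variant_04
LKKSPWTPEEEEILVDYIRKHGHANWRALPKQAGLIRCGKASKLRWTNYLKP
>r2r3_variant_05
LKKGPWTPEEDEILVDYMKKHGHGNWRALPKKGGLLRCGRSCRLRWANHLRP
>r2r3_variant_06
LKKAAWTPDEDEILVNYIKKHGHGNWRAVAQKASLIRCGKSCRLQWTDYLRP
>r2r3_variant_07
LKKGPWTPEDDQILVDFIKKHGYGNWRALPKKAGLLRCGKSCQFKWTNYLRP
>r2r3_variant_08
LKKGPWTPEEDEILVDFVKKHGHGNWRALPQKAGLVRCGKASRLRWTNYLRP
>r2r3_variant_09
LKQGPWTPEDDEMLVDYIKKHGNGNWKALAQKAAILRAGKSSRLKWTNYLQP
>r2r3_variant_10
LKKGPWTPEQDEMLVDYIKKHAYGNWRALPKKAGLIRCSKSARLRWTDFLRP
>r2r3_variant_11
LKKGPWSPEEDEMLMDYLKKNGHGNWRALPKKAGLFRCSQSCRLRWTNYLRP
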