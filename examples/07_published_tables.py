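"""Apply the screen rules to the published Arabidopsis candidate tables.

The eight printed steady-state trans-NAT/target pairs and the four printed
polysome-association pairs are fixed worked examples: the direction rule
(both members FC > 2 in either direction at padj < 0.1; positive when they
agree in sign) must yield exactly five positive and three negative
steady-state calls, and the translation rule (lincRNA DE plus a >= 30%
target polysome-association shift) four positive calls.
"""

from lincscreen.worked_examples import (
    STEADY_STATE_PAIRS,
    TRANSLATION_PAIRS,
    classify_steady_state_pairs,
    classify_translation_pairs,
)

ss = STEADY_STATE_PAIRS.assign(direction=classify_steady_state_pairs())
print("steady-state pairs:")
print(ss[["trans_nat", "target", "tNAT_FC", "trgt_FC", "direction"]].to_string(index=False))
print(f"-> {(ss['direction'] == 'positive').sum()} positive, "
      f"{(ss['direction'] == 'negative').sum()} negative")

tr = TRANSLATION_PAIRS.assign(direction=classify_translation_pairs())
print("\ntranslation pairs:")
print(tr[["trans_nat", "target", "tNAT_FC", "trgt_FC_PA", "direction"]].to_string(index=False))
print(f"-> {(tr['direction'] == 'positive').sum()} positive calls")
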