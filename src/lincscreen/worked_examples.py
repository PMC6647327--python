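"""Published Arabidopsis worked examples for the direction-classification rules.

These are the printed candidate tables from the Arabidopsis seedling
polysome-profiling study the screen thresholds come from: eight trans-NAT /
target-mRNA pairs evaluated at steady state and four pairs evaluated for
polysome-association (PA) shifts. They serve as fixed, hand-checkable inputs
for :func:`lincscreen.screens.classify_pair` and the translation-screen rule —
the published direction labels (five positive and three negative steady-state
pairs; four positive translation pairs) must be reproduced exactly.

Fold changes are condition-A-relative (down-regulation < 1); p-values are
BH-adjusted.
"""

from __future__ import annotations

import pandas as pd

STEADY_STATE_COLUMNS = ["trans_nat", "target", "tNAT_FC", "tNAT_pval", "trgt_FC", "trgt_pval", "comparison"]

#: eight trans-NAT / target pairs correlated with target mRNA steady-state level
STEADY_STATE_PAIRS = pd.DataFrame(
    [
        ("XLOC_003697", "AT4G28790", 2.80, 3.6e-9, 2.43, 2.9e-8, "Root ctrl_Shoot ctrl"),
        ("XLOC_000486", "AT1G66320", 2.27, 0.017, 3.88, 2.2e-4, "Root ctrl_Shoot ctrl"),
        ("XLOC_002538", "AT3G48640", 0.06, 6.5e-6, 0.21, 1.3e-6, "Root ctrl_Shoot ctrl"),
        ("XLOC_001309", "AT3G22370", 0.33, 0.0013, 0.28, 5.3e-12, "Root ctrl_Shoot ctrl"),
        ("XLOC_003241", "AT4G01770", 2.79, 0.0025, 4.57, 1.2e-12, "Root ctrl_Shoot ctrl"),
        ("XLOC_003681", "AT5G41380", 0.06, 8.6e-17, 4.73, 3.7e-8, "Root ctrl_Shoot ctrl"),
        ("XLOC_002538", "AT5G66670", 0.06, 6.5e-6, 3.70, 3.8e-10, "Root ctrl_Shoot ctrl"),
        ("XLOC_001125", "AT1G63350", 5.12, 1.8e-7, 0.44, 1.2e-5, "Root ABA_Root ctrl"),
    ],
    columns=STEADY_STATE_COLUMNS,
)

TRANSLATION_COLUMNS = [
    "trans_nat", "target", "tNAT_FC", "tNAT_pval", "trgt_FC", "trgt_pval",
    "trgt_FC_PA", "trgt_pval_PA", "comparison",
]

#: four trans-NAT / target pairs correlated with target polysome association
TRANSLATION_PAIRS = pd.DataFrame(
    [
        ("XLOC_002456", "AT5G24670", 2.06, 0.022, 0.76, 0.031, 1.53, 0.021, "Root ctrl_Shoot ctrl"),
        ("XLOC_002963", "AT3G27470", 2.98, 0.0014, 1.63, 1.0e-6, 1.41, 0.053, "Root ctrl_Shoot ctrl"),
        ("XLOC_002528", "AT3G10770", 4.91, 9.6e-9, 0.86, 0.33, 1.30, 0.086, "Low Pi_High Pi"),
        ("AT4G16355", "AT2G22260", 0.30, 0.0013, 1.00, 0.98, 0.73, 0.067, "Root ABA_Root ctrl"),
    ],
    columns=TRANSLATION_COLUMNS,
)


def classify_steady_state_pairs(
    pairs: pd.DataFrame | None = None, fc_thresh: float = 2.0, padj_thresh: float = 0.1
) -> pd.Series:
    """Direction of each steady-state pair under the screen rule."""
    from .screens import classify_pair

    pairs = STEADY_STATE_PAIRS if pairs is None else pairs
    out = []
    for _, row in pairs.iterrows():
        out.append(
            classify_pair(
                {"fc": row["tNAT_FC"], "padj": row["tNAT_pval"]},
                {"fc": row["trgt_FC"], "padj": row["trgt_pval"]},
                fc_thresh=fc_thresh,
                padj_thresh=padj_thresh,
            )
        )
    return pd.Series(out, index=pairs.index, name="direction")


def classify_translation_pairs(
    pairs: pd.DataFrame | None = None,
    fc_thresh: float = 2.0,
    padj_thresh: float = 0.1,
    pa_thresh: float = 1.3,
) -> pd.Series:
    """Direction of each translation pair under the screen rule.

    The lincRNA must pass the steady-state DE thresholds and the target the
    PA-shift thresholds (at least 30% in either direction); direction is
    positive when the two shifts agree in sign.
    """
    from .screens import _passes_de, _passes_pa

    pairs = TRANSLATION_PAIRS if pairs is None else pairs
    out = []
    for _, row in pairs.iterrows():
        ok = _passes_de(row["tNAT_FC"], row["tNAT_pval"], fc_thresh, padj_thresh) and _passes_pa(
            row["trgt_FC_PA"], row["trgt_pval_PA"], pa_thresh, padj_thresh
        )
        if not ok:
            out.append(None)
        else:
            out.append(
                "positive" if (row["tNAT_FC"] > 1.0) == (row["trgt_FC_PA"] > 1.0) else "negative"
            )
    return pd.Series(out, index=pairs.index, name="direction")
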