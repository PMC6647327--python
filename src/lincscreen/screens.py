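"""Directional regulatory candidate calls from DE/PA tables and homology hits.

Three screens turn upstream evidence into lincRNA -> target candidate calls:

* steady state: an antisense (trans-NAT) or chromatin-window (RNA:DNA) hit
  where both members are differentially expressed (fold change > 2 in either
  direction, adjusted p < 0.1) and both clear the normalized-count floor;
  direction is positive when both move the same way, negative otherwise,
* translation: the lincRNA is differentially expressed and the target's
  polysome-association ratio shifts by at least 30% (adjusted p < 0.1),
* neighbors: the same direction classification applied to lincRNA/neighbor
  pairs within the 10 kb window.

Each call carries the Pearson correlation of the pair's condition-mean
profiles across the full design; |r| > 0.6 marks the most robust candidates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .align import AlignmentHit
from .catalog import NeighborRecord
from .expression import CountMatrix, pearson_profile

CALL_COLUMNS = [
    "lincrna", "target", "interaction", "contrast", "direction",
    "tNAT_FC", "tNAT_pval", "trgt_FC", "trgt_pval",
    "trgt_FC_PA", "trgt_pval_PA", "pearson_r", "robust",
]


def _passes_de(fc: float, padj: float, fc_thresh: float, padj_thresh: float) -> bool:
    # two-fold in either direction, strict; padj strict
    return (fc > fc_thresh or fc < 1.0 / fc_thresh) and padj < padj_thresh


def classify_pair(de_a, de_b, fc_thresh: float = 2.0, padj_thresh: float = 0.1) -> str | None:
    """Direction of co-regulation for two DE results of the same contrast.

    Returns ``"positive"`` when both members pass the DE thresholds and move
    the same way, ``"negative"`` when they move oppositely, None otherwise.
    Accepts anything exposing ``fc``/``padj`` (a DE table row works).
    """
    fa, pa = float(de_a["fc"]), float(de_a["padj"])
    fb, pb = float(de_b["fc"]), float(de_b["padj"])
    if not (_passes_de(fa, pa, fc_thresh, padj_thresh) and _passes_de(fb, pb, fc_thresh, padj_thresh)):
        return None
    return "positive" if (fa > 1.0) == (fb > 1.0) else "negative"


def _contrast_label(contrast: tuple[str, str]) -> str:
    return f"{contrast[0]}_vs_{contrast[1]}"


def _dedupe_hits(hits: list[AlignmentHit]) -> list[AlignmentHit]:
    """Best hit per (lincRNA, target) pair, by score."""
    best: dict[tuple[str, str], AlignmentHit] = {}
    for h in hits:
        key = (h.query_id, h.subject_id)
        if key not in best or h.score > best[key].score:
            best[key] = h
    return [best[k] for k in sorted(best)]


def _pair_pearson(norm: CountMatrix | None, a: str, b: str) -> float:
    if norm is None:
        return float("nan")
    means = norm.condition_means()
    # the correlation is auxiliary: undefined for tiny designs, not an error
    if means.shape[1] < 3 or a not in means.index or b not in means.index:
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pearson_profile(means.loc[a].to_numpy(), means.loc[b].to_numpy())


def _floor_ok(norm: CountMatrix | None, locus: str, contrast, floor: float) -> bool:
    """Mean normalized count over the samples of the two compared conditions."""
    if norm is None or floor <= 0:
        return True
    if locus not in norm.data.index:
        return False
    cols = norm.samples_for(contrast[0]) + norm.samples_for(contrast[1])
    return float(norm.data.loc[locus, cols].mean()) > floor


def screen_steady_state(
    hits: list[AlignmentHit],
    de_tables: dict[tuple[str, str], pd.DataFrame],
    norm: CountMatrix,
    interaction: str = "rna_rna",
    floor: float = 10.0,
    fc_thresh: float = 2.0,
    padj_thresh: float = 0.1,
    robust_r: float = 0.6,
) -> pd.DataFrame:
    """Steady-state co-regulation screen over homology hits.

    For each deduplicated (lincRNA, target) hit and each contrast, the
    normalized-count floor is applied to both members, the pair is
    direction-classified, and the full-design Pearson correlation and
    robustness flag are attached.
    """
    rows = []
    pearson_cache: dict[tuple[str, str], float] = {}
    for hit in _dedupe_hits(hits):
        linc, target = hit.query_id, hit.subject_id
        for contrast, de in de_tables.items():
            if linc not in de.index or target not in de.index:
                warnings.warn(
                    f"{linc} or {target} absent from DE table {_contrast_label(contrast)}; skipped"
                )
                continue
            if not (_floor_ok(norm, linc, contrast, floor) and _floor_ok(norm, target, contrast, floor)):
                continue
            direction = classify_pair(de.loc[linc], de.loc[target], fc_thresh, padj_thresh)
            if direction is None:
                continue
            key = (linc, target)
            if key not in pearson_cache:
                pearson_cache[key] = _pair_pearson(norm, linc, target)
            r = pearson_cache[key]
            rows.append(
                {
                    "lincrna": linc,
                    "target": target,
                    "interaction": interaction,
                    "contrast": _contrast_label(contrast),
                    "direction": direction,
                    "tNAT_FC": float(de.loc[linc, "fc"]),
                    "tNAT_pval": float(de.loc[linc, "padj"]),
                    "trgt_FC": float(de.loc[target, "fc"]),
                    "trgt_pval": float(de.loc[target, "padj"]),
                    "trgt_FC_PA": float("nan"),
                    "trgt_pval_PA": float("nan"),
                    "pearson_r": r,
                    "robust": bool(abs(r) > robust_r) if not math.isnan(r) else False,
                }
            )
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def _passes_pa(pa_fc: float, padj: float, pa_thresh: float, padj_thresh: float) -> bool:
    # "at least 30% increase or decrease": inclusive on the ratio threshold
    return (pa_fc >= pa_thresh or pa_fc <= 1.0 / pa_thresh) and padj < padj_thresh


def screen_translation(
    hits: list[AlignmentHit],
    de_tables: dict[tuple[str, str], pd.DataFrame],
    pa_tables: dict[tuple[str, str], pd.DataFrame],
    norm_total: CountMatrix | None = None,
    norm_polysomal: CountMatrix | None = None,
    fc_thresh: float = 2.0,
    padj_thresh: float = 0.1,
    pa_thresh: float = 1.3,
    robust_r: float = 0.6,
) -> pd.DataFrame:
    """Translation screen: lincRNA DE plus a target polysome-association shift.

    Direction is positive when the lincRNA fold change and the target PA
    shift agree in sign. The attached Pearson correlates lincRNA steady state
    with the target's PA ratio across conditions when both matrices are
    supplied.
    """
    pa_ratio_means: pd.DataFrame | None = None
    t_means: pd.DataFrame | None = None
    if norm_total is not None and norm_polysomal is not None:
        t_means = norm_total.condition_means()
        p_means = norm_polysomal.condition_means()
        common = t_means.index.intersection(p_means.index)
        pa_ratio_means = (p_means.loc[common] + 0.5) / (t_means.loc[common] + 0.5)
    rows = []
    for hit in _dedupe_hits(hits):
        linc, target = hit.query_id, hit.subject_id
        for contrast, de in de_tables.items():
            pa = pa_tables.get(contrast)
            if pa is None:
                continue
            if linc not in de.index or target not in pa.index:
                warnings.warn(
                    f"{linc} or {target} absent from tables {_contrast_label(contrast)}; skipped"
                )
                continue
            linc_fc = float(de.loc[linc, "fc"])
            linc_padj = float(de.loc[linc, "padj"])
            pa_fc = float(pa.loc[target, "pa_fc"])
            pa_padj = float(pa.loc[target, "padj"])
            if not (_passes_de(linc_fc, linc_padj, fc_thresh, padj_thresh)
                    and _passes_pa(pa_fc, pa_padj, pa_thresh, padj_thresh)):
                continue
            direction = "positive" if (linc_fc > 1.0) == (pa_fc > 1.0) else "negative"
            r = float("nan")
            if pa_ratio_means is not None and t_means is not None and t_means.shape[1] >= 3:
                if linc in t_means.index and target in pa_ratio_means.index:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        r = pearson_profile(
                            t_means.loc[linc].to_numpy(), pa_ratio_means.loc[target].to_numpy()
                        )
            target_fc = float(de.loc[target, "fc"]) if target in de.index else float("nan")
            target_padj = float(de.loc[target, "padj"]) if target in de.index else float("nan")
            rows.append(
                {
                    "lincrna": linc,
                    "target": target,
                    "interaction": "rna_rna",
                    "contrast": _contrast_label(contrast),
                    "direction": direction,
                    "tNAT_FC": linc_fc,
                    "tNAT_pval": linc_padj,
                    "trgt_FC": target_fc,
                    "trgt_pval": target_padj,
                    "trgt_FC_PA": pa_fc,
                    "trgt_pval_PA": pa_padj,
                    "pearson_r": r,
                    "robust": bool(abs(r) > robust_r) if not math.isnan(r) else False,
                }
            )
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def screen_neighbors(
    neighbors: list[NeighborRecord],
    de_tables: dict[tuple[str, str], pd.DataFrame],
    norm: CountMatrix | None = None,
    fc_thresh: float = 2.0,
    padj_thresh: float = 0.1,
    robust_r: float = 0.6,
) -> pd.DataFrame:
    """Direction classification for each lincRNA/neighbor-gene pair per contrast."""
    rows = []
    pearson_cache: dict[tuple[str, str], float] = {}
    for nb in neighbors:
        for contrast, de in de_tables.items():
            if nb.lincrna_id not in de.index or nb.gene_id not in de.index:
                continue
            direction = classify_pair(
                de.loc[nb.lincrna_id], de.loc[nb.gene_id], fc_thresh, padj_thresh
            )
            if direction is None:
                continue
            key = (nb.lincrna_id, nb.gene_id)
            if key not in pearson_cache:
                pearson_cache[key] = _pair_pearson(norm, nb.lincrna_id, nb.gene_id)
            r = pearson_cache[key]
            rows.append(
                {
                    "lincrna": nb.lincrna_id,
                    "target": nb.gene_id,
                    "interaction": "neighbor",
                    "contrast": _contrast_label(contrast),
                    "direction": direction,
                    "tNAT_FC": float(de.loc[nb.lincrna_id, "fc"]),
                    "tNAT_pval": float(de.loc[nb.lincrna_id, "padj"]),
                    "trgt_FC": float(de.loc[nb.gene_id, "fc"]),
                    "trgt_pval": float(de.loc[nb.gene_id, "padj"]),
                    "trgt_FC_PA": float("nan"),
                    "trgt_pval_PA": float("nan"),
                    "pearson_r": r,
                    "robust": bool(abs(r) > robust_r) if not math.isnan(r) else False,
                }
            )
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def build_network(
    calls: pd.DataFrame, norm: CountMatrix | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Node and edge tables for the candidate-regulation network.

    Nodes are lincRNAs and coding targets with their maximum condition-mean
    expression; edges are deduplicated per (pair, interaction), keeping the
    direction and the list of supporting contrasts.
    """
    node_cols = ["id", "node_type", "max_expression"]
    edge_cols = ["lincrna", "target", "interaction", "direction", "contrasts", "pearson_r"]
    if calls.empty:
        return pd.DataFrame(columns=node_cols), pd.DataFrame(columns=edge_cols)
    means = norm.condition_means() if norm is not None else None

    def _max_expr(locus: str) -> float:
        if means is None or locus not in means.index:
            return float("nan")
        return float(means.loc[locus].max())

    nodes = []
    for lid in sorted(set(calls["lincrna"])):
        nodes.append({"id": lid, "node_type": "lincRNA", "max_expression": _max_expr(lid)})
    for gid in sorted(set(calls["target"]) - set(calls["lincrna"])):
        nodes.append({"id": gid, "node_type": "coding", "max_expression": _max_expr(gid)})

    edges = []
    for (linc, target, interaction), sub in calls.groupby(
        ["lincrna", "target", "interaction"], sort=True
    ):
        directions = list(dict.fromkeys(sub["direction"]))
        edges.append(
            {
                "lincrna": linc,
                "target": target,
                "interaction": interaction,
                "direction": directions[0] if len(directions) == 1 else "mixed",
                "contrasts": ";".join(sorted(set(sub["contrast"]))),
                "pearson_r": float(sub["pearson_r"].iloc[0]),
            }
        )
    return pd.DataFrame(nodes, columns=node_cols), pd.DataFrame(edges, columns=edge_cols)
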