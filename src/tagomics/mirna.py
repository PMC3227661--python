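"""miRNA target-consensus filtering and pairing with differential expression.

Predicted miRNA-target pairs from three prediction tools are kept when at
least two tools agree; that set is intersected with the union of the
experimentally supported databases, yielding the robust target set.  The
consensus is computed at (miRNA, gene) pair granularity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "PredictionSet",
    "ConsensusResult",
    "normalize_mirna_id",
    "consensus_targets",
    "pair_with_de",
]


def normalize_mirna_id(mirna_id: str) -> str:
    """Case-insensitive miRNA identifier with the species prefix stripped.

    -3p/-5p arm suffixes are left untouched (no arm guessing).
    """
    s = mirna_id.strip().lower()
    if s.startswith("hsa-"):
        s = s[4:]
    return s


@dataclass
class PredictionSet:
    """A source of miRNA -> target-gene pairs (prediction tool or database)."""

    source_name: str
    pairs: frozenset  # of (mirna_id, gene_id), ids normalized

    @classmethod
    def from_pairs(cls, source_name: str, pairs: Iterable[tuple[str, str]]) -> "PredictionSet":
        norm = frozenset(
            (normalize_mirna_id(m), g.strip()) for m, g in pairs if m.strip() and g.strip()
        )
        if len(norm) < len(frozenset(pairs)):
            pass  # duplicates / id-case variants collapse silently
        return cls(source_name=source_name, pairs=norm)


@dataclass
class ConsensusResult:
    """Pairs supported by >=2 prediction sources and >=1 experimental source."""

    pairs: frozenset
    provenance: dict  # pair -> {"pred": [...], "exp": [...]} supporting source names


def consensus_targets(
    predictions: Sequence[PredictionSet],
    experimental: Sequence[PredictionSet],
    min_prediction_sources: int = 2,
) -> ConsensusResult:
    """Robust target filter: (pairs in >= ``min_prediction_sources`` of the
    prediction sets) intersected with (union of the experimental sets).

    The canonical configuration is 3 prediction tools and 2 experimentally
    supported databases; any >= ``min_prediction_sources`` predictions and
    >= 1 experimental source are accepted.
    """
    if len(predictions) < min_prediction_sources or len(experimental) < 1:
        warnings.warn("empty or insufficient input sources; consensus is empty")
        return ConsensusResult(pairs=frozenset(), provenance={})
    votes: dict[tuple[str, str], set[str]] = {}
    for ps in predictions:
        for pair in ps.pairs:
            votes.setdefault(pair, set()).add(ps.source_name)
    agreed = {pair for pair, sources in votes.items() if len(sources) >= min_prediction_sources}
    exp_support: dict[tuple[str, str], set[str]] = {}
    for es in experimental:
        for pair in es.pairs:
            exp_support.setdefault(pair, set()).add(es.source_name)
    result = agreed & set(exp_support)
    provenance = {
        pair: {"pred": sorted(votes[pair]), "exp": sorted(exp_support[pair])}
        for pair in result
    }
    return ConsensusResult(pairs=frozenset(result), provenance=provenance)


def pair_with_de(
    consensus: ConsensusResult,
    de_mirnas: pd.DataFrame,
    de_mrnas: pd.DataFrame,
    require_anticorrelation: bool = False,
) -> tuple[pd.DataFrame, tuple[int, int]]:
    """Restrict consensus pairs to differentially expressed miRNAs and report
    each target gene's differential status.

    ``de_mirnas`` / ``de_mrnas`` are differential tables (columns
    ``locus_id``, ``log2_ratio``, ``significant``, ``direction``).  With
    ``require_anticorrelation`` only opposite-direction pairs (e.g. miRNA
    down, target up) are kept.  Returns the paired table and the summary
    (#distinct miRNAs, #distinct target genes).
    """
    mir = de_mirnas.copy()
    mir["_id"] = [normalize_mirna_id(m) for m in mir["locus_id"]]
    mir = mir.set_index("_id")
    de_mir = mir[mir["significant"]]
    genes = de_mrnas.set_index("locus_id")
    rows = []
    for mirna, gene in sorted(consensus.pairs):
        if mirna not in de_mir.index:
            continue
        m_log2 = float(de_mir.loc[mirna, "log2_ratio"])
        m_dir = str(de_mir.loc[mirna, "direction"])
        if gene in genes.index:
            g_log2 = float(genes.loc[gene, "log2_ratio"])
            g_dir = str(genes.loc[gene, "direction"])
            g_sig = bool(genes.loc[gene, "significant"])
        else:
            g_log2, g_dir, g_sig = float("nan"), "none", False
        if require_anticorrelation:
            if not (g_sig and {m_dir, g_dir} == {"up", "down"}):
                continue
        prov = consensus.provenance[(mirna, gene)]
        rows.append(
            {
                "mirna_id": mirna,
                "gene_id": gene,
                "n_pred_sources": len(prov["pred"]),
                "sources": ";".join(prov["pred"] + prov["exp"]),
                "mirna_log2": m_log2,
                "mirna_direction": m_dir,
                "gene_log2": g_log2,
                "gene_direction": g_dir,
                "gene_significant": g_sig,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "mirna_id",
            "gene_id",
            "n_pred_sources",
            "sources",
            "mirna_log2",
            "mirna_direction",
            "gene_log2",
            "gene_direction",
            "gene_significant",
        ],
    )
    summary = (table["mirna_id"].nunique(), table["gene_id"].nunique()) if len(table) else (0, 0)
    return table, summary
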