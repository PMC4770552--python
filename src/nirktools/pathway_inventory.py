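"""Denitrification / DNRA pathway classification and co-occurrence statistics.

Each genome in the cohort carries at least one nitrite reductase gene
(nirK by construction of the cohort, or nirS) — a denitrifier *sensu
stricto*.  Downstream modularity is classified from the presence of nitric
oxide reductase (nor) and nitrous oxide reductase (nosZ):

    nor and nosZ  -> complete denitrification (nir + nor + nos)
    nosZ only     -> -nor
    nor only      -> -nos
    neither       -> -nor/-nos

DNRA capability is read from nrfA (respiratory) and nirB (fermentative),
each paired with whichever nitrate reductases are present (napA and/or
narG); the labels are deliberately non-exclusive — a genome with nrfA and
nirB contributes to both branches, and one with napA and narG to both
pairings, which is the only reading under which per-label percentages can
sum above the combined denitrification+DNRA percentage.

Co-occurrence of gene pairs is tested with the exact hypergeometric
(probabilistic co-occurrence) model plus the phi coefficient, the Pearson
correlation of the two presence/absence vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

GENE_FLAGS = ("nirS", "nor", "nosZ", "napA", "narG", "nrfA", "nirB", "nirV")

DENIT_CATEGORIES = ("complete", "no_nor", "no_nos", "no_nor_no_nos")
DNRA_LABELS = ("nap_nrfA", "nar_nrfA", "nrfA_only", "nap_nirB", "nar_nirB", "nirB_only")


@dataclass(frozen=True)
class GenomeInventory:
    """Presence/absence record for one genome (nirK as an integer copy count)."""

    genome_id: str
    phylum: str = ""
    nirK_copies: int = 1
    nirS: bool = False
    nor: bool = False
    nosZ: bool = False
    napA: bool = False
    narG: bool = False
    nrfA: bool = False
    nirB: bool = False
    nirV: bool = False

    def __post_init__(self) -> None:
        if self.nirK_copies < 0:
            raise ValueError("nirK_copies must be >= 0")

    def flag(self, gene: str) -> bool:
        if gene == "nirK":
            return self.nirK_copies >= 1
        return bool(getattr(self, gene))


@dataclass(frozen=True)
class PathwayCall:
    denit_category: str
    dnra_labels: frozenset[str]
    combined: bool


def classify_genome(inv: GenomeInventory) -> PathwayCall:
    """Assign the denitrification category and DNRA labels for one genome.

    Rejects genomes lacking any nitrite reductase: without nirK or nirS the
    organism is not a denitrifier *sensu stricto* and does not belong in the
    cohort.
    """
    if inv.nirK_copies < 1 and not inv.nirS:
        raise ValueError(
            f"genome {inv.genome_id!r} has no nitrite reductase (nirK or nirS); "
            "not a denitrifier sensu stricto"
        )
    if inv.nor and inv.nosZ:
        cat = "complete"
    elif inv.nosZ:
        cat = "no_nor"
    elif inv.nor:
        cat = "no_nos"
    else:
        cat = "no_nor_no_nos"
    labels = set()
    for gene, tag in (("nrfA", "nrfA"), ("nirB", "nirB")):
        if not inv.flag(gene):
            continue
        paired = False
        if inv.napA:
            labels.add(f"nap_{tag}")
            paired = True
        if inv.narG:
            labels.add(f"nar_{tag}")
            paired = True
        if not paired:
            labels.add(f"{tag}_only")
    combined = inv.nrfA or inv.nirB
    return PathwayCall(denit_category=cat, dnra_labels=frozenset(labels), combined=combined)


def _pct(numer: int, denom: int) -> float:
    """Percentage to one decimal, rounding half away from zero."""
    if denom == 0:
        return 0.0
    exact = Decimal(100) * Decimal(numer) / Decimal(denom)
    return float(exact.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def summarize_cohort(
    inventories: Sequence[GenomeInventory],
    calls: Sequence[PathwayCall] | None = None,
) -> pd.DataFrame:
    """Per-phylum and Total percentages of pathway categories.

    Columns: n, pct_multi_copy, one column per denitrification category,
    one per DNRA label, pct_combined, pct_nirV.  The Total row is computed
    from the raw calls, never from rounded per-phylum values.
    """
    if not inventories:
        raise ValueError("empty cohort")
    if calls is None:
        calls = [classify_genome(inv) for inv in inventories]
    rows = {}
    groups: dict[str, list[int]] = {}
    for k, inv in enumerate(inventories):
        groups.setdefault(inv.phylum or "unknown", []).append(k)
    order = sorted(groups)
    for phylum in order + ["Total"]:
        idx = groups[phylum] if phylum != "Total" else list(range(len(inventories)))
        n = len(idx)
        row = {"n": n}
        row["pct_multi_copy"] = _pct(
            sum(1 for k in idx if inventories[k].nirK_copies >= 2), n
        )
        for cat in DENIT_CATEGORIES:
            row[f"pct_{cat}"] = _pct(sum(1 for k in idx if calls[k].denit_category == cat), n)
        for label in DNRA_LABELS:
            row[f"pct_{label}"] = _pct(sum(1 for k in idx if label in calls[k].dnra_labels), n)
        row["pct_combined"] = _pct(sum(1 for k in idx if calls[k].combined), n)
        row["pct_nirV"] = _pct(sum(1 for k in idx if inventories[k].nirV), n)
        rows[phylum] = row
    return pd.DataFrame(rows).T


@dataclass
class CooccurrenceStat:
    """Exact hypergeometric co-occurrence test plus phi for one gene pair."""

    gene_a: str
    gene_b: str
    n: int
    n1: int
    n2: int
    j_obs: int
    expected: float
    p_lt: float
    p_gt: float
    phi: float | None
    phi_defined: bool = True


def cooccurrence_test(
    x: Sequence[int] | np.ndarray,
    y: Sequence[int] | np.ndarray,
    gene_a: str = "a",
    gene_b: str = "b",
) -> CooccurrenceStat:
    """Probabilistic co-occurrence of two binary presence vectors.

    With marginals N1, N2 out of N genomes, the number of joint presences
    under random placement is hypergeometric:
    P(j) = C(N1, j) C(N-N1, N2-j) / C(N, N2).  ``p_lt`` is the probability
    of observing at most ``j_obs`` joint presences, ``p_gt`` of at least
    ``j_obs`` (the tails overlap at j_obs, so p_lt + p_gt >= 1).  ``phi``
    is the Pearson correlation of the binaries, undefined (flagged) when
    either vector is constant.
    """
    x = np.asarray(x, dtype=int)
    y = np.asarray(y, dtype=int)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 2:
        raise ValueError("need at least two genomes")
    if not (set(np.unique(x)) <= {0, 1} and set(np.unique(y)) <= {0, 1}):
        raise ValueError("vectors must be binary")
    n1, n2 = int(x.sum()), int(y.sum())
    j_obs = int((x & y).sum())
    dist = hypergeom(n, n1, n2)
    p_lt = float(dist.cdf(j_obs))
    p_gt = float(dist.sf(j_obs - 1))
    phi_defined = len(set(x)) > 1 and len(set(y)) > 1
    phi = float(np.corrcoef(x, y)[0, 1]) if phi_defined else None
    return CooccurrenceStat(
        gene_a=gene_a,
        gene_b=gene_b,
        n=n,
        n1=n1,
        n2=n2,
        j_obs=j_obs,
        expected=n1 * n2 / n,
        p_lt=min(p_lt, 1.0),
        p_gt=min(p_gt, 1.0),
        phi=phi,
        phi_defined=phi_defined,
    )


def pairwise_gene_screen(
    table: Sequence[GenomeInventory],
    genes: Sequence[str] = ("napA", "narG", "nrfA", "nirB"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All-pairs co-occurrence screen with Benjamini–Hochberg correction.

    One row per unordered gene pair; the BH-adjusted q-values are computed
    across pairs on the smaller tail (min of p_lt, p_gt, capped at 1 after
    doubling), a two-sided summary appropriate for screening.
    """
    if len(genes) < 2:
        raise ValueError("need at least two genes")
    vectors = {
        g: np.array([int(inv.flag(g)) for inv in table], dtype=int) for g in genes
    }
    stats = [
        cooccurrence_test(vectors[a], vectors[b], a, b)
        for a, b in combinations(genes, 2)
    ]
    p_two = [min(1.0, 2.0 * min(s.p_lt, s.p_gt)) for s in stats]
    reject, q, _, _ = multipletests(p_two, alpha=alpha, method="fdr_bh")
    return pd.DataFrame(
        {
            "gene_a": [s.gene_a for s in stats],
            "gene_b": [s.gene_b for s in stats],
            "N": [s.n for s in stats],
            "N1": [s.n1 for s in stats],
            "N2": [s.n2 for s in stats],
            "j_obs": [s.j_obs for s in stats],
            "expected": [s.expected for s in stats],
            "p_lt": [s.p_lt for s in stats],
            "p_gt": [s.p_gt for s in stats],
            "p_two_sided": p_two,
            "q_bh": q,
            "significant": reject,
            "phi": [s.phi if s.phi_defined else np.nan for s in stats],
        }
    )


def read_inventory_tsv(path) -> list[GenomeInventory]:
    """Read a genome inventory TSV (columns: genome_id, phylum, nirK, gene flags)."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        out.append(
            GenomeInventory(
                genome_id=str(row["genome_id"]),
                phylum=str(row.get("phylum", "")),
                nirK_copies=int(row.get("nirK", 1)),
                **{g: bool(int(row.get(g, 0))) for g in GENE_FLAGS},
            )
        )
    return out


def write_inventory_tsv(table: Sequence[GenomeInventory], path) -> None:
    rows = []
    for inv in table:
        row = {"genome_id": inv.genome_id, "phylum": inv.phylum, "nirK": inv.nirK_copies}
        row.update({g: int(inv.flag(g)) for g in GENE_FLAGS})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
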