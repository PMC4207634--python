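"""Counting-based dN/dS estimation (Nei-Gojobori 1986).

Synonymous and non-synonymous sites are counted per codon as the
fraction of possible single-nucleotide changes that preserve the
encoded amino acid (changes creating stop codons count as
non-synonymous so that sites always sum to three per codon). Observed
differences between codons are apportioned over all shortest mutational
pathways with equal weight, skipping pathways that pass through stop
codons. Proportions are corrected for multiple hits with the
Jukes-Cantor formula d = -(3/4) ln(1 - 4p/3) and omega = dN/dS.

Group-wise contrasts pool the raw counts over all within-group pairs
before ratio-taking, with a seeded bootstrap over codon columns for
confidence intervals. This transparent estimator supports directional
contrasts (purifying vs relaxed selection between gene groups); it is
not a maximum-likelihood branch model and its omega values are not
comparable to ML branch estimates at strong divergence.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from ._seq import CODON_TO_AA, STOP_CODONS


@dataclass
class CodonAlignment:
    taxa: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa and rows differ in length")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("rows must be equal length")

    @property
    def n_codons(self) -> int:
        return len(self.rows[0]) // 3 if self.rows else 0

    def codons(self, i: int) -> list[str]:
        row = self.rows[i]
        return [row[j : j + 3] for j in range(0, len(row), 3)]


def validate_codon_alignment(rows: dict[str, str]) -> CodonAlignment:
    """Check frame and stop-codon policy of an in-frame nucleotide MSA.

    Row length must be divisible by 3. A trailing stop codon column is
    trimmed; an internal stop is fatal, reported with its row id. Gap
    codons '---' are preserved.
    """
    taxa = list(rows)
    seqs = [rows[t].upper() for t in taxa]
    if len({len(s) for s in seqs}) > 1:
        raise ValueError("rows must be equal length")
    if not seqs or len(seqs[0]) % 3 != 0:
        raise ValueError("alignment length must be divisible by 3")
    n_codons = len(seqs[0]) // 3
    # trailing stop column: trim if any row ends with a stop
    if n_codons and any(s[-3:] in STOP_CODONS for s in seqs):
        seqs = [s[:-3] for s in seqs]
        n_codons -= 1
    for t, s in zip(taxa, seqs):
        for j in range(n_codons):
            codon = s[3 * j : 3 * j + 3]
            if codon in STOP_CODONS:
                raise ValueError(
                    f"internal stop codon in row {t!r} at codon {j}"
                )
    return CodonAlignment(taxa=taxa, rows=seqs)


@dataclass
class PathwayCount:
    N_sites: float
    S_sites: float
    Nd: float
    Sd: float


@dataclass
class OmegaEstimate:
    dN: float
    dS: float
    omega: float | None
    undefined: bool = False
    saturated: bool = False


def _codon_site_counts(codon: str) -> tuple[float, float]:
    """(synonymous, non-synonymous) site counts for one codon.

    Each of the nine possible single-nucleotide changes contributes 1/3
    of a site; changes to stop codons count as non-synonymous.
    """
    aa = CODON_TO_AA[codon]
    syn = 0.0
    for pos in range(3):
        for alt in "ACGT":
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            if CODON_TO_AA[mutant] == aa:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


def _pathway_changes(c1: str, c2: str) -> tuple[float, float]:
    """(Sd, Nd) between two codons, averaged over shortest pathways.

    Pathways passing through stop codons are discarded; if every
    pathway is blocked, all pathways are used as a fallback.
    """
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    if not diffs:
        return 0.0, 0.0
    results = []
    for order in itertools.permutations(diffs):
        cur = c1
        syn = non = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if CODON_TO_AA[nxt] == "*":
                blocked = True
            if CODON_TO_AA[cur] == CODON_TO_AA[nxt]:
                syn += 1
            else:
                non += 1
            cur = nxt
        results.append((blocked, syn, non))
    usable = [(s, n) for b, s, n in results if not b]
    if not usable:
        usable = [(s, n) for _, s, n in results]
    sd = sum(s for s, _ in usable) / len(usable)
    nd = sum(n for _, n in usable) / len(usable)
    return sd, nd


def jukes_cantor(p: float) -> tuple[float, bool]:
    """JC correction d = -(3/4) ln(1 - 4p/3); flags saturation."""
    if p < 0:
        raise ValueError("proportion must be >= 0")
    if 4 * p / 3 >= 1:
        return math.inf, True
    return -0.75 * math.log(1 - 4 * p / 3), False


def _usable_codon(c: str) -> bool:
    return c in CODON_TO_AA and CODON_TO_AA[c] != "*"


def ng86_pairwise(row_i: str, row_j: str) -> tuple[PathwayCount, OmegaEstimate]:
    """Nei-Gojobori counting estimate for one aligned sequence pair.

    Gap or ambiguous codons are pairwise-deleted. Site counts are the
    average of the two sequences' per-codon counts.
    """
    if len(row_i) != len(row_j) or len(row_i) % 3:
        raise ValueError("rows must be equal length and in frame")
    S = N = Sd = Nd = 0.0
    for k in range(0, len(row_i), 3):
        c1, c2 = row_i[k : k + 3].upper(), row_j[k : k + 3].upper()
        if not (_usable_codon(c1) and _usable_codon(c2)):
            continue
        s1, n1 = _codon_site_counts(c1)
        s2, n2 = _codon_site_counts(c2)
        S += 0.5 * (s1 + s2)
        N += 0.5 * (n1 + n2)
        sd, nd = _pathway_changes(c1, c2)
        Sd += sd
        Nd += nd
    counts = PathwayCount(N_sites=N, S_sites=S, Nd=Nd, Sd=Sd)
    est = _counts_to_estimate(counts)
    return counts, est


def _counts_to_estimate(counts: PathwayCount) -> OmegaEstimate:
    if counts.N_sites == 0 or counts.S_sites == 0:
        return OmegaEstimate(math.nan, math.nan, None, undefined=True)
    dN, satN = jukes_cantor(counts.Nd / counts.N_sites)
    dS, satS = jukes_cantor(counts.Sd / counts.S_sites)
    saturated = satN or satS
    if dS == 0 or saturated:
        return OmegaEstimate(dN, dS, None, undefined=True, saturated=saturated)
    return OmegaEstimate(dN, dS, dN / dS)


@dataclass
class GroupScheme:
    """Disjoint named taxon groups for selection contrasts."""

    groups: dict[str, list[str]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for name, taxa in self.groups.items():
            if seen & set(taxa):
                raise ValueError(f"group {name!r} overlaps another group")
            seen |= set(taxa)


@dataclass
class GroupOmega:
    estimate: OmegaEstimate
    counts: PathwayCount
    n_pairs: int
    ci: tuple[float, float] | None = None


def _per_codon_pair_counts(aln: CodonAlignment, taxa: list[str]) -> np.ndarray:
    """Per-codon-column (S, N, Sd, Nd) summed over all pairs in ``taxa``.

    Shape (n_codons, 4); supports column bootstrap without re-walking
    pathways.
    """
    idx = [aln.taxa.index(t) for t in taxa]
    codon_rows = [aln.codons(i) for i in idx]
    n_codons = aln.n_codons
    out = np.zeros((n_codons, 4))
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            for k in range(n_codons):
                c1, c2 = codon_rows[a][k], codon_rows[b][k]
                if not (_usable_codon(c1) and _usable_codon(c2)):
                    continue
                s1, n1 = _codon_site_counts(c1)
                s2, n2 = _codon_site_counts(c2)
                sd, nd = _pathway_changes(c1, c2)
                out[k] += (0.5 * (s1 + s2), 0.5 * (n1 + n2), sd, nd)
    return out


def group_omega(
    aln: CodonAlignment,
    scheme: GroupScheme,
    bootstrap: int = 200,
    seed: int = 0,
) -> dict[str, GroupOmega]:
    """Pooled within-group omega with a codon-column bootstrap CI.

    Raw synonymous/non-synonymous sites and differences are summed over
    all within-group pairs before the Jukes-Cantor correction and the
    ratio, so sparse pairs do not produce unstable per-pair ratios.
    Groups whose rows are all identical report omega as undefined.
    """
    rng = np.random.default_rng(seed)
    results: dict[str, GroupOmega] = {}
    for name, taxa in scheme.groups.items():
        if len(taxa) < 2:
            raise ValueError(f"group {name!r} needs >= 2 taxa")
        missing = set(taxa) - set(aln.taxa)
        if missing:
            raise ValueError(f"group {name!r} has unknown taxa {sorted(missing)}")
        per_codon = _per_codon_pair_counts(aln, taxa)
        total = per_codon.sum(axis=0)
        counts = PathwayCount(S_sites=total[0], N_sites=total[1],
                              Sd=total[2], Nd=total[3])
        est = _counts_to_estimate(counts)
        ci = None
        if bootstrap > 0 and est.omega is not None:
            n_codons = per_codon.shape[0]
            omegas = []
            for _ in range(bootstrap):
                cols = rng.integers(0, n_codons, size=n_codons)
                t = per_codon[cols].sum(axis=0)
                e = _counts_to_estimate(
                    PathwayCount(S_sites=t[0], N_sites=t[1], Sd=t[2], Nd=t[3])
                )
                if e.omega is not None:
                    omegas.append(e.omega)
            if omegas:
                ci = (
                    float(np.percentile(omegas, 2.5)),
                    float(np.percentile(omegas, 97.5)),
                )
        n_pairs = len(taxa) * (len(taxa) - 1) // 2
        results[name] = GroupOmega(estimate=est, counts=counts,
                                   n_pairs=n_pairs, ci=ci)
    return results
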