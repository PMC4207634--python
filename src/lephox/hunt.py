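"""Six-frame homeodomain profile search, deduplication and classification.

A gapless 60-column position-specific scoring matrix is built from a
seed alignment of homeodomains and slid across all six translation
frames of each contig. Hit significance uses an empirical Gumbel fit to
shuffled-window scores, preserving the ordering semantics of a BLAST
E-value threshold without Karlin-Altschul theory. Hits are collapsed
greedily by coordinate overlap and classified against a labelled
reference panel by p-distance, with the position-10 serine diagnostic
for the Hox3 (zen/Shx) lineage.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gumbel_r

from ._jtt import jtt_frequencies
from ._seq import AA_INDEX, AMINO_ACIDS, encode

logger = logging.getLogger(__name__)

HD_LEN = 60  # homeodomain length in residues

# aa index layout for translated frames: 0-19 residues, 20 stop, 21 invalid
_STOP, _INVALID = 20, 21


def _default_background() -> np.ndarray:
    """JTT equilibrium amino-acid frequencies as scan background."""
    return jtt_frequencies()


@dataclass
class ProteinProfile:
    """Log-odds profile over a gapless protein block.

    ``log_odds`` is (length x 20) in natural-log units against
    ``background``; translated stop/invalid columns score -inf so any
    window containing them is voided.
    """

    length: int
    log_odds: np.ndarray
    background: np.ndarray
    pseudocount: float
    calibration_seed: int = 12345
    _gumbel: tuple[float, float] | None = field(default=None, repr=False)

    def score_peptide(self, peptide: str) -> float:
        if len(peptide) != self.length:
            raise ValueError("peptide length does not match profile")
        total = 0.0
        for i, aa in enumerate(peptide):
            j = AA_INDEX.get(aa)
            if j is None:
                return -math.inf
            total += self.log_odds[i, j]
        return total

    def gumbel_params(self, n_shuffles: int = 1000) -> tuple[float, float]:
        """Fit a Gumbel null to scores of random background windows.

        Calibrated once per profile with a fixed seed; cached.
        """
        if self._gumbel is None:
            rng = np.random.default_rng(self.calibration_seed)
            draws = rng.choice(20, size=(n_shuffles, self.length), p=self.background)
            scores = self.log_odds[np.arange(self.length), draws].sum(axis=1)
            loc, scale = gumbel_r.fit(scores)
            self._gumbel = (float(loc), float(scale))
        return self._gumbel

    def evalue(self, score: float, n_windows: int) -> float:
        loc, scale = self.gumbel_params()
        return float(n_windows * gumbel_r.sf(score, loc, scale))


def build_profile(
    seed_alignment: list[str],
    pseudocount: float = 0.1,
    background: np.ndarray | None = None,
) -> ProteinProfile:
    """Build a log-odds profile from a gapless protein alignment.

    Column score for residue a: ln(((f_a + pc * bg_a) / (1 + pc)) / bg_a)
    where f_a is the observed column frequency and pc the pseudocount
    mass; pc -> infinity flattens all scores to zero.
    """
    if not seed_alignment:
        raise ValueError("empty seed alignment")
    length = len(seed_alignment[0])
    if any(len(s) != length for s in seed_alignment):
        raise ValueError("ragged seed alignment")
    if any("-" in s for s in seed_alignment):
        raise ValueError("seed alignment must be gapless")
    bg = np.asarray(background if background is not None else _default_background())
    if bg.shape != (20,) or not np.isclose(bg.sum(), 1.0):
        raise ValueError("background must be 20 frequencies summing to 1")
    n = len(seed_alignment)
    freqs = np.zeros((length, 20))
    for s in seed_alignment:
        for i, aa in enumerate(s):
            j = AA_INDEX.get(aa)
            if j is None:
                raise ValueError(f"non-standard residue {aa!r} in seed alignment")
            freqs[i, j] += 1.0 / n
    log_odds = np.log((freqs + pseudocount * bg) / (1 + pseudocount) / bg)
    return ProteinProfile(
        length=length, log_odds=log_odds, background=bg, pseudocount=pseudocount
    )


@dataclass
class ProfileHit:
    contig_id: str
    start: int  # 0-based half-open, forward strand
    end: int
    strand: str
    frame: int
    score: float
    evalue_like: float
    peptide: str


_CODON_TO_AAIDX = None


def _codon_aa_lut() -> np.ndarray:
    """64-entry codon-code -> aa-index lookup (20 = stop)."""
    global _CODON_TO_AAIDX
    if _CODON_TO_AAIDX is None:
        from ._seq import BASES, CODON_TO_AA

        lut = np.empty(64, dtype=np.int8)
        for i, a in enumerate(BASES):
            for j, b in enumerate(BASES):
                for l, c in enumerate(BASES):
                    aa = CODON_TO_AA[a + b + c]
                    lut[16 * i + 4 * j + l] = _STOP if aa == "*" else AA_INDEX[aa]
        _CODON_TO_AAIDX = lut
    return _CODON_TO_AAIDX


def _translate_frames(codes: np.ndarray) -> dict[tuple[str, int], np.ndarray]:
    """aa-index arrays for all six frames of a 2-bit coded contig."""
    lut = _codon_aa_lut()
    out = {}
    for strand in "+-":
        if strand == "+":
            c = codes
        else:
            rc = codes[::-1]
            c = np.where(rc == 255, 255, 3 - rc).astype(np.uint8)
        for frame in range(3):
            sub = c[frame:]
            n_codons = sub.size // 3
            tri = sub[: n_codons * 3].reshape(n_codons, 3)
            bad = (tri == 255).any(axis=1)
            idx = (tri[:, 0].astype(np.int32) * 16
                   + tri[:, 1].astype(np.int32) * 4 + tri[:, 2])
            aa = np.where(bad, _INVALID, lut[np.clip(idx, 0, 63)]).astype(np.int8)
            out[(strand, frame)] = aa
    return out


def scan_contigs(
    contigs: dict[str, str],
    profile: ProteinProfile,
    threshold_evalue: float = 1e-6,
) -> list[ProfileHit]:
    """Sliding-window profile scan of all six frames of every contig.

    Windows containing stop codons or ambiguous bases are voided.
    ``evalue_like`` is the expected number of random windows at or above
    the hit score over all windows scanned in this call. Hits are
    returned sorted by score (descending); coordinates are forward
    strand, 0-based half-open, spanning 3 x profile-length nucleotides.
    """
    if not contigs:
        raise ValueError("no contigs supplied")
    L = profile.length
    pad = np.full((profile.log_odds.shape[0], 2), -np.inf)
    lo = np.hstack([profile.log_odds, pad])  # stop/invalid -> -inf

    scored = []  # (contig, strand, frame, scores array, aa array)
    n_windows = 0
    for contig_id, seq in contigs.items():
        if len(seq) < 3 * L:
            logger.info("contig %s shorter than %d nt; skipped", contig_id, 3 * L)
            continue
        codes = encode(seq)
        frames = _translate_frames(codes)
        for (strand, frame), aa in frames.items():
            W = aa.size - L + 1
            if W <= 0:
                continue
            scores = np.zeros(W)
            aa_idx = aa.astype(np.intp)
            for i in range(L):
                scores += lo[i, aa_idx[i : i + W]]
            n_windows += int(np.isfinite(scores).sum())
            scored.append((contig_id, strand, frame, scores, aa))

    # translate the e-value threshold into a score cutoff once
    loc, scale = profile.gumbel_params()
    if n_windows == 0:
        return []
    tail = min(max(threshold_evalue / n_windows, 0.0), 1.0)
    cutoff = float(gumbel_r.isf(tail, loc, scale)) if tail > 0 else np.inf

    hits: list[ProfileHit] = []
    for contig_id, strand, frame, scores, aa in scored:
        for off in np.nonzero(scores >= cutoff)[0]:
            off = int(off)
            score = float(scores[off])
            ev = profile.evalue(score, n_windows)
            contig_len = len(contigs[contig_id])
            if strand == "+":
                start = frame + 3 * off
                end = start + 3 * L
            else:
                end = contig_len - (frame + 3 * off)
                start = end - 3 * L
            peptide = "".join(
                AMINO_ACIDS[j] if j < 20 else "*X"[j - 20]
                for j in aa[off : off + L]
            )
            hits.append(
                ProfileHit(
                    contig_id=contig_id, start=start, end=end, strand=strand,
                    frame=frame, score=score, evalue_like=ev, peptide=peptide,
                )
            )
    hits.sort(key=lambda h: (-h.score, h.contig_id, h.start))
    return hits


def dedupe_hits(hits: list[ProfileHit], min_overlap: float = 0.5) -> list[ProfileHit]:
    """Greedy best-first collapse of overlapping hits on one contig.

    Hits sharing >= ``min_overlap`` of their span (relative to the
    shorter hit) with an already-kept higher-scoring hit are dropped.
    """
    kept: list[ProfileHit] = []
    for h in sorted(hits, key=lambda h: (-h.score, h.contig_id, h.start)):
        redundant = False
        for k in kept:
            if k.contig_id != h.contig_id:
                continue
            ov = min(k.end, h.end) - max(k.start, h.start)
            shorter = min(k.end - k.start, h.end - h.start)
            if shorter > 0 and ov / shorter >= min_overlap:
                redundant = True
                break
        if not redundant:
            kept.append(h)
    return kept


@dataclass
class HitClassification:
    hit: ProfileHit
    assigned_class: str
    diagnostic_flags: dict[str, bool]
    nearest_reference: tuple[str, float]


def p_distance(a: str, b: str) -> float:
    """Mismatch fraction over pairwise-valid (non-gap) positions."""
    if len(a) != len(b):
        raise ValueError("sequences must be aligned to equal length")
    used = mism = 0
    for x, y in zip(a, b):
        if x in "-X" or y in "-X":
            continue
        used += 1
        mism += x != y
    if used == 0:
        return math.nan
    return mism / used


def classify_hit(
    hit: ProfileHit,
    reference_set: list[tuple[str, str, str]],
    distance_ceiling: float = 0.6,
) -> HitClassification:
    """Assign a Hox class to a hit by nearest labelled reference.

    ``reference_set`` rows are (id, class, 60-aa sequence). Ties in
    distance go to the class with more reference members, then to the
    lexicographically smaller class. Peptides with >10% ambiguous
    positions, or farther than ``distance_ceiling`` from every
    reference, are labelled 'unknown'. The S10 flag records the
    Hox3-diagnostic serine at homeodomain position 10.
    """
    if not reference_set:
        raise ValueError("empty reference set")
    pep = hit.peptide
    s10 = len(pep) >= 10 and pep[9] == "S"
    flags = {"S10": s10}
    ambiguous = sum(aa not in AMINO_ACIDS for aa in pep)
    if ambiguous > 0.1 * len(pep):
        return HitClassification(hit, "unknown", flags, ("", math.nan))
    class_sizes: dict[str, int] = {}
    for _, cls, _ in reference_set:
        class_sizes[cls] = class_sizes.get(cls, 0) + 1
    best = None
    for ref_id, cls, seq in reference_set:
        d = p_distance(pep, seq)
        key = (d, -class_sizes[cls], cls, ref_id)
        if best is None or key < best[0]:
            best = (key, ref_id, cls, d)
    _, ref_id, cls, d = best
    if not math.isfinite(d) or d > distance_ceiling:
        return HitClassification(hit, "unknown", flags, (ref_id, d))
    return HitClassification(hit, cls, flags, (ref_id, d))


def build_class_profiles(
    reference_set: list[tuple[str, str, str]], pseudocount: float = 0.1
) -> dict[str, ProteinProfile]:
    """One profile per reference class.

    Pooling divergent classes into a single profile dilutes every
    column and weakens true-member scores, so the search runs one
    sharp profile per class — the profile analogue of querying with
    multiple per-class homeodomains.
    """
    by_class: dict[str, list[str]] = {}
    for _, cls, seq in reference_set:
        by_class.setdefault(cls, []).append(seq)
    return {
        cls: build_profile(seqs, pseudocount=pseudocount)
        for cls, seqs in by_class.items()
    }


def hunt_genome(
    contigs: dict[str, str],
    reference_set: list[tuple[str, str, str]],
    threshold_evalue: float = 1e-6,
    distance_ceiling: float = 0.6,
) -> list[HitClassification]:
    """Full search driver: per-class scans, merge, dedupe, classify."""
    profiles = build_class_profiles(reference_set)
    pooled: list[ProfileHit] = []
    for cls in sorted(profiles):
        pooled.extend(scan_contigs(contigs, profiles[cls], threshold_evalue))
    hits = dedupe_hits(pooled)
    return [
        classify_hit(h, reference_set, distance_ceiling=distance_ceiling)
        for h in hits
    ]


# ---------------------------------------------------------------------------
# neighbor joining (orthology-assignment support tree)
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    taxa: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("distance matrix shape does not match taxa")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if not np.isfinite(v).all() or (v < -1e-12).any():
            raise ValueError("distances must be finite and non-negative")
        self.values = v


class _Node:
    __slots__ = ("label", "children", "sort_key")

    def __init__(self, label=None, children=None, sort_key=""):
        self.label = label
        self.children = children or []  # list of (node, branch_length)
        self.sort_key = sort_key

    def newick(self) -> str:
        if not self.children:
            return self.label
        inner = ",".join(f"{c.newick()}:{bl:.6f}" for c, bl in self.children)
        return f"({inner})"


def nj_tree(dm: DistanceMatrix) -> str:
    """Neighbor-joining agglomeration, returned as an unrooted newick.

    Ties in the Q-criterion are broken toward the lexicographically
    smallest pair of subtree labels, making output deterministic.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes = [_Node(label=t, sort_key=t) for t in dm.taxa]
    D = dm.values.copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        r = {i: sum(D[i, j] for j in active if j != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                q = (m - 2) * D[i, j] - r[i] - r[j]
                pair_key = tuple(sorted((nodes[i].sort_key, nodes[j].sort_key)))
                key = (round(q, 12), pair_key)
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        vi = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        vj = D[i, j] - vi
        vi, vj = max(vi, 0.0), max(vj, 0.0)
        new = _Node(
            children=[(nodes[i], vi), (nodes[j], vj)],
            sort_key=min(nodes[i].sort_key, nodes[j].sort_key),
        )
        # grow D with the new node's distances
        k = D.shape[0]
        D = np.pad(D, ((0, 1), (0, 1)))
        for x in active:
            if x in (i, j):
                continue
            D[k, x] = D[x, k] = 0.5 * (D[i, x] + D[j, x] - D[i, j])
        nodes.append(new)
        active = [x for x in active if x not in (i, j)] + [k]

    i, j, k = active
    # three-point closed form for the final star
    bi = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    bj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    bk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    parts = sorted(
        zip((nodes[i], nodes[j], nodes[k]), (bi, bj, bk)),
        key=lambda p: p[0].sort_key,
    )
    inner = ",".join(f"{nd.newick()}:{max(bl, 0.0):.6f}" for nd, bl in parts)
    return f"({inner});"
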