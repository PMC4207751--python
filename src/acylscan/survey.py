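"""Iterative comparative-genomic survey with reciprocal-best-hit validation.

The survey emulates an iterative sequence-similarity search: starting
from functionally characterised seed queries, each proteome is searched
by exact Smith-Waterman local alignment (BLOSUM62, affine gaps 11/1, the
standard protein-search defaults); hits below the E-value cutoff are
validated and added; from the second round onward the accumulated members
are condensed into a motif-anchored position-specific scoring matrix
(PSSM) that is rescored against everything not yet validated, until an
iteration adds nothing.

Validation of a candidate is threefold, mirroring how candidate
homologues are vetted in comparative surveys: (1) the similarity score
must clear the E-value (or relative PSSM score) threshold; (2) the
candidate must display motif evidence — by default two of the
subclass's informative signature motifs (see :func:`motif_evidence`);
(3) a reciprocal search against the reference proteome must return one
of the seed sequences as the best hit, beating the best non-seed
reference score by a margin (reciprocal best hit).  E-values follow the
Karlin-Altschul form ``K * m * n * exp(-lambda * S)`` with the published
gapped-BLOSUM62 constants; ``n`` is the total residue count of the
searched database.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from functools import lru_cache
from math import exp, inf
from typing import Mapping

import numpy as np
import pandas as pd

from .alphabet import AA20, AA_SET, background_composition
from .grammar import match_at
from .profiles import SubclassProfile
from .scan import scan_chain

logger = logging.getLogger(__name__)

_AA_INDEX = {aa: i for i, aa in enumerate(AA20)}


@dataclass(frozen=True)
class SurveyParams:
    """Thresholds and scoring constants of the survey."""

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = 0.267
    k: float = 0.041
    evalue_cutoff: float = 0.05
    reciprocal_cutoff: float = 10.0
    rbh_margin: float = 10.0
    pssm_threshold: float = 0.3
    pseudocount: float = 0.5
    min_motif_evidence: int = 2
    min_motif_bits: float = 15.0
    background: str = "uniform"


@dataclass(frozen=True)
class AlignmentResult:
    """One local alignment between a query and a subject."""

    query_id: str
    subject_id: str
    score: float
    query_span: tuple[int, int]
    subject_span: tuple[int, int]
    identity: float
    e_value: float


@lru_cache(maxsize=8)
def _aligner(mode: str, matrix_name: str, gap_open: int, gap_extend: int):
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    aligner.mode = mode
    # affine gap of length g costs open + g * extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def karlin_altschul_evalue(
    score: float, m: int, n: int, lam: float = 0.267, k: float = 0.041
) -> float:
    """Expected number of chance local alignments scoring >= ``score``."""
    return k * m * n * exp(-lam * score)


def _validate_seq(seq: str, name: str) -> None:
    bad = set(seq) - AA_SET - {"X"}
    if bad:
        raise ValueError(
            f"sequence {name!r} contains residues outside the standard "
            f"alphabet plus X: {sorted(bad)}"
        )


def smith_waterman(
    a: str,
    b: str,
    params: SurveyParams = SurveyParams(),
    query_id: str = "query",
    subject_id: str = "subject",
    db_length: int | None = None,
) -> AlignmentResult:
    """Optimal local alignment of two proteins with affine gap costs.

    ``db_length`` overrides the subject length in the E-value (set it to
    the total database size when the pair comes from a database search).
    """
    if not a or not b:
        raise ValueError("empty sequence")
    if params.gap_open <= 0 or params.gap_extend <= 0:
        raise ValueError("gap penalties must be positive")
    _validate_seq(a, query_id)
    _validate_seq(b, subject_id)
    aligner = _aligner(
        "local", params.matrix_name, params.gap_open, params.gap_extend
    )
    score = float(aligner.score(a, b))
    n = db_length if db_length is not None else len(b)
    if score <= 0.0:
        return AlignmentResult(
            query_id=query_id, subject_id=subject_id, score=0.0,
            query_span=(0, 0), subject_span=(0, 0), identity=0.0,
            e_value=karlin_altschul_evalue(0.0, len(a), n, params.lam,
                                           params.k),
        )
    alignment = aligner.align(a, b)[0]
    counts = alignment.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    identity = counts.identities / columns if columns else 0.0
    a_blocks, b_blocks = alignment.aligned
    query_span = (int(a_blocks[0][0]), int(a_blocks[-1][1]))
    subject_span = (int(b_blocks[0][0]), int(b_blocks[-1][1]))
    return AlignmentResult(
        query_id=query_id, subject_id=subject_id, score=score,
        query_span=query_span, subject_span=subject_span,
        identity=identity,
        e_value=karlin_altschul_evalue(score, len(a), n, params.lam,
                                       params.k),
    )


def local_score(a: str, b: str, params: SurveyParams = SurveyParams()) -> float:
    """Raw Smith-Waterman score only (fast path, no traceback)."""
    aligner = _aligner(
        "local", params.matrix_name, params.gap_open, params.gap_extend
    )
    return float(aligner.score(a, b))


def best_hit(
    query: str,
    proteome: Mapping[str, str],
    params: SurveyParams = SurveyParams(),
    query_id: str = "query",
) -> AlignmentResult | None:
    """Best-scoring subject in ``proteome`` passing the E-value cutoff.

    The E-value uses the total residue count of the proteome as the
    database length.  Equal scores are broken toward the
    lexicographically smallest subject id.
    """
    if not proteome:
        raise ValueError("empty proteome")
    db_length = sum(len(s) for s in proteome.values())
    best_id: str | None = None
    best_score = -inf
    for subject_id in sorted(proteome):
        score = local_score(query, proteome[subject_id], params)
        if score > best_score:
            best_id, best_score = subject_id, score
    assert best_id is not None
    e_value = karlin_altschul_evalue(
        best_score, len(query), db_length, params.lam, params.k
    )
    if e_value > params.evalue_cutoff:
        return None
    return smith_waterman(
        query, proteome[best_id], params, query_id=query_id,
        subject_id=best_id, db_length=db_length,
    )


def reciprocal_validate(
    hit: str,
    reference_proteome: Mapping[str, str],
    seed_ids: frozenset[str] | set[str],
    params: SurveyParams = SurveyParams(),
    margin: float = 0.0,
) -> bool:
    """True iff the hit's best reference match is one of the seeds.

    The reciprocal search uses the permissive retrieval cutoff
    (``reciprocal_cutoff``, default 10): validation is about the *rank*
    of the returned sequence, not its significance.  A positive
    ``margin`` additionally requires the best seed score to beat the
    best non-seed reference score by that many raw score units, which
    suppresses rank-by-luck among near-tied random scores.
    """
    missing = set(seed_ids) - set(reference_proteome)
    if missing:
        raise ValueError(f"seed ids not in reference proteome: {missing}")
    relaxed = replace(params, evalue_cutoff=params.reciprocal_cutoff)
    result = best_hit(hit, reference_proteome, relaxed)
    if result is None or result.subject_id not in seed_ids:
        return False
    if margin > 0:
        nonseed = {
            name: seq for name, seq in reference_proteome.items()
            if name not in seed_ids
        }
        if nonseed:
            best_other = max(
                local_score(hit, seq, params) for seq in nonseed.values()
            )
            if result.score - best_other < margin:
                return False
    return True


@dataclass(frozen=True)
class MotifPSSM:
    """Motif-anchored log-odds profile over the four motif blocks."""

    blocks: tuple[np.ndarray, ...]  # each (block_length, 20)
    dbm_ranges: tuple[tuple[int, int], ...]

    @property
    def max_score(self) -> float:
        return float(sum(block.max(axis=1).sum() for block in self.blocks))

    def score(self, seq: str, top_k: int = 8) -> float:
        """Best in-order, non-overlapping placement of the four blocks,
        with the soft spacing penalty between adjacent blocks."""
        encoded = np.fromiter(
            (_AA_INDEX.get(ch, 20) for ch in seq), dtype=np.int64,
            count=len(seq),
        )
        candidates: list[list[tuple[int, float]]] = []
        for block in self.blocks:
            length = block.shape[0]
            n_off = len(seq) - length + 1
            if n_off <= 0:
                return -inf
            padded = np.hstack([block, np.zeros((length, 1))])
            scores = np.zeros(n_off)
            for k in range(length):
                scores += padded[k, encoded[k:k + n_off]]
            order = np.argsort(-scores, kind="stable")[:top_k]
            candidates.append(
                [(int(o), float(scores[o])) for o in sorted(order)]
            )
        lengths = [block.shape[0] for block in self.blocks]
        best_prev: dict[int, float] = {}
        for off, s in candidates[0]:
            best_prev[off] = max(best_prev.get(off, -inf), s)
        for k in range(1, 4):
            lo, hi = self.dbm_ranges[k - 1]
            best_here: dict[int, float] = {}
            for off, s in candidates[k]:
                best = -inf
                for poff, pscore in best_prev.items():
                    pend = poff + lengths[k - 1]
                    d = off - pend
                    if d < 0:
                        continue
                    penalty = 0.0
                    if d < lo:
                        penalty = 0.5 * (lo - d)
                    elif d > hi:
                        penalty = 0.5 * (d - hi)
                    best = max(best, pscore - penalty)
                if best > -inf:
                    best_here[off] = best + s
            if not best_here:
                return -inf
            best_prev = best_here
        return max(best_prev.values())


def build_profile(
    validated: Mapping[str, str],
    prof: SubclassProfile,
    pseudocount: float = 0.5,
    background: str | Mapping[str, float] = "uniform",
) -> MotifPSSM:
    """Build the motif-anchored PSSM from chain-complete family members.

    Every member must yield a full four-motif chain for ``prof``; columns
    corresponding to optional pattern positions are weighted by how many
    members actually occupy them.  Column log-odds are
    ``log2((c + a*q) / ((N + 20a) * q))`` with pseudocount ``a`` and
    background frequency ``q``.
    """
    if not validated:
        raise ValueError("no sequences to build a profile from")
    if isinstance(background, str):
        bg = background_composition(background)
    else:
        bg = dict(background)
    q = np.array([bg[aa] for aa in AA20])

    offenders = []
    windows: dict[str, list[str]] = {}
    for name, seq in validated.items():
        chain = scan_chain(seq, prof, dbm_mode="soft", min_motifs=4)
        if chain is None:
            offenders.append(name)
            continue
        windows[name] = [
            seq[off:off + length] for off, length in chain.placements
        ]
    if offenders:
        raise ValueError(
            "members without a full motif chain: " + ", ".join(offenders)
        )

    blocks = []
    for k, pattern in enumerate(prof.motifs):
        npos = len(pattern.positions)
        optional_idx = [
            i for i, p in enumerate(pattern.positions) if p.optional
        ]
        counts = np.zeros((npos, 20))
        occupancy = np.zeros(npos)
        for member_windows in windows.values():
            window = member_windows[k]
            if len(window) == npos:
                cols = range(npos)
            elif npos - len(window) == len(optional_idx):
                cols = [i for i in range(npos) if i not in optional_idx]
            else:
                raise ValueError(
                    f"window {window!r} incompatible with motif "
                    f"{pattern.label} of {prof.subclass}"
                )
            for col, ch in zip(cols, window):
                idx = _AA_INDEX.get(ch)
                if idx is not None:
                    counts[col, idx] += 1
                    occupancy[col] += 1
        block = np.zeros((npos, 20))
        for col in range(npos):
            if occupancy[col] == 0:
                continue  # column unobserved: neutral scores
            numer = counts[col] + pseudocount * q
            denom = (occupancy[col] + 20 * pseudocount) * q
            block[col] = np.log2(numer / denom)
        blocks.append(block)
    return MotifPSSM(blocks=tuple(blocks), dbm_ranges=prof.dbm_ranges)


def motif_evidence(
    seq: str, prof: SubclassProfile, min_bits: float = 15.0
) -> int:
    """Number of informative motifs of the profile occurring in ``seq``.

    Only patterns carrying at least ``min_bits`` of specificity count:
    the weakly constrained motif IV patterns (around 10 bits) occur by
    chance in a few hundred residues of random sequence and carry no
    evidential weight on their own.
    """
    found = 0
    for pattern in prof.motifs:
        if pattern.max_score < min_bits:
            continue
        for i in range(len(seq) - pattern.min_length + 1):
            if match_at(pattern, seq, i):
                found += 1
                break
    return found


@dataclass
class SurveyResult:
    """Validated hits per family and proteome, with the iteration log."""

    validated: dict[str, dict[str, tuple[str, ...]]]
    iterations: int
    additions: pd.DataFrame
    presence: pd.DataFrame


def iterative_survey(
    proteomes: Mapping[str, Mapping[str, str]],
    seeds: Mapping[str, Mapping[str, str]],
    reference_proteome: Mapping[str, str],
    profiles: Mapping[str, SubclassProfile],
    params: SurveyParams = SurveyParams(),
) -> SurveyResult:
    """Run the iterative survey to its fixpoint.

    ``seeds`` maps each family to its labelled seed sequences, which must
    all be present in ``reference_proteome``.  ``profiles`` supplies the
    motif grammar used for motif evidence and PSSM anchoring.  The
    validated sets grow monotonically and the loop stops at the first
    iteration that adds nothing, so termination is guaranteed.
    """
    if not seeds:
        raise ValueError("no seed families")
    for family in seeds:
        if family not in profiles:
            raise ValueError(f"no profile for seed family {family!r}")
        missing = set(seeds[family]) - set(reference_proteome)
        if missing:
            raise ValueError(
                f"seeds of {family!r} missing from reference: {missing}"
            )
    db_length = {
        name: sum(len(s) for s in prots.values())
        for name, prots in proteomes.items()
    }
    validated: dict[str, set[tuple[str, str]]] = {f: set() for f in seeds}
    ref_db_length = sum(len(s) for s in reference_proteome.values())
    ref_scores: dict[tuple[str, str], dict[str, float]] = {}
    all_seed_ids = {
        sid for family in seeds for sid in seeds[family]
    }
    log_rows: list[dict[str, object]] = []
    iteration = 0

    def reciprocal_ok(key: tuple[str, str], seq: str, family: str) -> bool:
        # one reference scan per candidate, reused across families
        if key not in ref_scores:
            ref_scores[key] = {
                sid: local_score(seq, sseq, params)
                for sid, sseq in reference_proteome.items()
            }
        scores = ref_scores[key]
        best_id = min(scores, key=lambda sid: (-scores[sid], sid))
        if best_id not in seeds[family]:
            return False
        e = karlin_altschul_evalue(
            scores[best_id], len(seq), ref_db_length, params.lam, params.k
        )
        if e > params.reciprocal_cutoff:
            return False
        nonseed = [
            s for sid, s in scores.items() if sid not in all_seed_ids
        ]
        if nonseed and scores[best_id] - max(nonseed) < params.rbh_margin:
            return False
        return True

    while True:
        iteration += 1
        added = 0
        pssms = {}
        if iteration > 1:
            for family in seeds:
                members = dict(seeds[family])
                for pname, pid in sorted(validated[family]):
                    members[f"{pname}/{pid}"] = proteomes[pname][pid]
                # only chain-complete members carry profile signal
                complete = {
                    name: seq for name, seq in members.items()
                    if scan_chain(seq, profiles[family]) is not None
                }
                pssms[family] = build_profile(
                    complete, profiles[family],
                    pseudocount=params.pseudocount,
                    background=params.background,
                )
        for family in seeds:
            prof = profiles[family]
            # the evidence requirement cannot exceed what the profile
            # offers (motif IV patterns are too weak to count at all)
            n_informative = sum(
                1 for pat in prof.motifs
                if pat.max_score >= params.min_motif_bits
            )
            evidence_required = min(
                params.min_motif_evidence, n_informative
            )
            for pname in sorted(proteomes):
                for pid in sorted(proteomes[pname]):
                    key = (pname, pid)
                    if key in validated[family]:
                        continue
                    seq = proteomes[pname][pid]
                    if iteration == 1:
                        hit_score = -inf
                        hit_e = inf
                        for seed_seq in seeds[family].values():
                            score = local_score(seed_seq, seq, params)
                            e = karlin_altschul_evalue(
                                score, len(seed_seq), db_length[pname],
                                params.lam, params.k,
                            )
                            if e < hit_e:
                                hit_score, hit_e = score, e
                        if hit_e > params.evalue_cutoff:
                            continue
                        method, method_score = "sw", hit_score
                    else:
                        pssm = pssms[family]
                        score = pssm.score(seq)
                        if score < params.pssm_threshold * pssm.max_score:
                            continue
                        method, method_score = "pssm", score
                    if motif_evidence(
                        seq, prof, params.min_motif_bits
                    ) < evidence_required:
                        continue
                    if not reciprocal_ok(key, seq, family):
                        continue
                    validated[family].add(key)
                    added += 1
                    log_rows.append({
                        "iteration": iteration, "family": family,
                        "proteome": pname, "protein_id": pid,
                        "method": method,
                        "score": round(float(method_score), 2),
                    })
        logger.info("survey iteration %d: %d additions", iteration, added)
        if added == 0:
            break

    families = list(seeds)
    proteome_names = list(proteomes)
    presence = pd.DataFrame(
        [
            [
                any(pname == p for p, _ in validated[family])
                for pname in proteome_names
            ]
            for family in families
        ],
        index=families, columns=proteome_names,
    )
    by_family = {
        family: {
            pname: tuple(
                sorted(pid for p, pid in validated[family] if p == pname)
            )
            for pname in proteome_names
        }
        for family in families
    }
    additions = pd.DataFrame(
        log_rows,
        columns=["iteration", "family", "proteome", "protein_id", "method",
                 "score"],
    )
    return SurveyResult(
        validated=by_family, iterations=iteration,
        additions=additions, presence=presence,
    )
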