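"""Labelled synthetic proteins and proteomes for exercising the pipeline.

A planted family member is assembled as::

    N-flank + motif I + gap(dbm1) + motif II + gap(dbm2)
            + motif III + gap(dbm3) + motif IV + C-flank [+ PTS1]

with motif residues drawn uniformly from each pattern position's allowed
set, inter-motif spacings drawn uniformly from the profile's DBM
intervals, and flank/gap residues drawn from the background composition
(uniform by default, which makes the scanner's specificity weights
exact).  Substitution noise is applied after assembly; in the default
``conservative`` mode it never touches the diagnostic features (motif
hallmark residues and a planted PTS1 tripeptide), in ``harsh`` mode it
can hit anything.  Noise draws depend only on the seed and the position,
so raising the noise level strictly grows the set of mutated sites —
corruption at different levels is nested and comparable.

There is no indel process beyond the single optional motif position and
no rate heterogeneity: the generator reproduces the statistical structure
the analysis relies on, not realistic sequence evolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alphabet import AA20, background_composition
from .profiles import SUBCLASS_ORDER, SubclassProfile
from .pts1 import detect_pts1

_CANONICAL_PTS1 = ("SAC", "KRH", "LM")
_RELAXED_PTS1 = ("GPT", "KRH", "IF")  # the additions beyond canonical


@dataclass(frozen=True)
class FamilySpec:
    """Sampling plan for one synthetic subclass family."""

    subclass: str
    n: int = 10
    length_range: tuple[int, int] = (350, 650)
    background: str = "uniform"
    noise: float = 0.0
    noise_mode: str = "conservative"  # conservative | harsh
    pts1: str = "none"  # none | canonical | relaxed
    divergence: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0.0 <= self.noise < 1.0:
            raise ValueError("noise must be in [0, 1)")
        if self.noise_mode not in ("conservative", "harsh"):
            raise ValueError(f"unknown noise_mode {self.noise_mode!r}")
        if self.pts1 not in ("none", "canonical", "relaxed"):
            raise ValueError(f"unknown pts1 option {self.pts1!r}")


def _bg_sampler(background: str):
    comp = background_composition(background)
    letters = np.array(list(AA20))
    probs = np.array([comp[aa] for aa in AA20])
    probs = probs / probs.sum()

    def draw(rng: np.random.Generator, n: int) -> str:
        return "".join(letters[rng.choice(20, size=n, p=probs)])

    return draw


def _sample_motif(
    pattern, rng: np.random.Generator
) -> tuple[str, list[int]]:
    """One motif instance plus the pattern-column index of each residue."""
    residues = []
    columns = []
    for idx, pos in enumerate(pattern.positions):
        if pos.optional and rng.random() < 0.5:
            continue
        allowed = sorted(pos.allowed)
        residues.append(allowed[rng.integers(0, len(allowed))])
        columns.append(idx)
    return "".join(residues), columns


def _sample_pts1(kind: str, rng: np.random.Generator) -> str:
    sets = []
    for canon, extra in zip(_CANONICAL_PTS1, _RELAXED_PTS1):
        sets.append(canon if kind == "canonical" else canon + extra)
    return "".join(s[rng.integers(0, len(s))] for s in sets)


def mutate_sequence(
    seq: str,
    rate: float,
    rng: np.random.Generator,
    protect: frozenset[int] | set[int] = frozenset(),
) -> str:
    """Per-position substitution at the given rate, sparing ``protect``.

    One uniform draw and one replacement draw are consumed per position
    regardless of the rate, so mutation sets at different rates (same
    rng state) are nested.
    """
    u = rng.random(len(seq))
    repl = rng.integers(0, 19, len(seq))
    out = list(seq)
    for i, ch in enumerate(out):
        if i in protect or u[i] >= rate:
            continue
        others = AA20.replace(ch, "") if ch in AA20 else AA20
        out[i] = others[repl[i] % len(others)]
    return "".join(out)


def generate_family(
    spec: FamilySpec, prof: SubclassProfile
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Generate ``spec.n`` labelled members of one subclass family.

    Returns ``(records, truth)`` where ``records`` is a list of
    ``(id, sequence)`` pairs and ``truth`` records the planted motif
    offsets (0-based), lengths, DBM values and PTS1 tripeptide.
    """
    if spec.subclass != prof.subclass:
        raise ValueError(
            f"spec subclass {spec.subclass!r} does not match profile "
            f"{prof.subclass!r}"
        )
    lo_len, hi_len = spec.length_range
    tail = 3 if spec.pts1 != "none" else 0
    max_core = sum(len(m) for m in prof.motifs) + sum(
        hi for _, hi in prof.dbm_ranges
    )
    if hi_len < max_core + tail:
        raise ValueError(
            f"length range {spec.length_range} cannot fit the motif chain "
            f"plus spacings (needs up to {max_core + tail})"
        )
    draw_bg = _bg_sampler(spec.background)
    rng_base = np.random.default_rng(
        np.random.SeedSequence([int(spec.seed), 0])
    )
    rng_noise = np.random.default_rng(
        np.random.SeedSequence([int(spec.seed), 1])
    )
    records: list[tuple[str, str]] = []
    rows: list[dict[str, object]] = []
    for i in range(spec.n):
        dbms = [
            int(rng_base.integers(lo, hi + 1))
            for lo, hi in prof.dbm_ranges
        ]
        motifs = [_sample_motif(m, rng_base) for m in prof.motifs]
        core = sum(len(m) for m, _ in motifs) + sum(dbms)
        total = int(rng_base.integers(max(lo_len, core + tail), hi_len + 1))
        flank_total = total - core - tail
        n_flank = int(rng_base.integers(0, flank_total + 1))
        c_flank = flank_total - n_flank
        tri = _sample_pts1(spec.pts1, rng_base) if tail else ""

        parts = [draw_bg(rng_base, n_flank)]
        offsets = []
        pos = n_flank
        for k, (motif, _) in enumerate(motifs):
            offsets.append(pos)
            parts.append(motif)
            pos += len(motif)
            if k < 3:
                parts.append(draw_bg(rng_base, dbms[k]))
                pos += dbms[k]
        parts.append(draw_bg(rng_base, c_flank))
        parts.append(tri)
        seq = "".join(parts)
        if spec.pts1 == "none":
            # a member declared signal-free must not end in a chance
            # PTS1-like tripeptide; redraw C-terminal flank residues
            # until the tail is negative (motif IV endings never are)
            n_redraw = min(c_flank, 3)
            while n_redraw and detect_pts1(seq).positive:
                seq = seq[:len(seq) - n_redraw] + draw_bg(rng_base, n_redraw)

        protected: set[int] = set()
        if spec.noise_mode == "conservative":
            for k, (motif, cols) in enumerate(motifs):
                hallmark = set(prof.motifs[k].hallmark_positions())
                for rel, col in enumerate(cols):
                    if col in hallmark:
                        protected.add(offsets[k] + rel)
            if tail:
                protected.update(range(len(seq) - 3, len(seq)))
        if spec.noise > 0:
            seq = mutate_sequence(
                seq, spec.noise, rng_noise, protect=frozenset(protected)
            )
        else:
            # keep the noise stream position-aligned across noise levels
            rng_noise.random(len(seq))
            rng_noise.integers(0, 19, len(seq))

        name = f"{spec.subclass}_{i:03d}"
        records.append((name, seq))
        row: dict[str, object] = {
            "id": name, "subclass": spec.subclass, "length": len(seq),
        }
        for k, label in enumerate(("I", "II", "III", "IV")):
            row[f"off_{label}"] = offsets[k]
            row[f"len_{label}"] = len(motifs[k][0])
        for k in range(3):
            row[f"dbm_{k + 1}"] = dbms[k]
        row["pts1"] = spec.pts1
        row["pts1_tripeptide"] = tri
        rows.append(row)
    return records, pd.DataFrame(rows)


def generate_decoys(
    n: int,
    length_range: tuple[int, int] = (150, 600),
    composition: str = "uniform",
    seed: int = 0,
    prefix: str = "decoy",
) -> list[tuple[str, str]]:
    """i.i.d. background sequences with no planted structure."""
    if n < 1:
        raise ValueError("n must be >= 1")
    draw_bg = _bg_sampler(composition)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2]))
    lo, hi = length_range
    out = []
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        out.append((f"{prefix}_{i:04d}", draw_bg(rng, length)))
    return out


#: per-proteome subclass membership plans emulating survey taxa: a
#: Saccharomycetaceae-like proteome whose whole mitoGPAT/GDPAT/DHAPAT
#: branch is absent, fungi with the novel GDPATs, metazoans with the
#: mito/DHAPAT pair, a reduced intracellular parasite with one microsomal
#: GPAT as its sole acyltransferase, and an all-decoy control.
PRESET_PLANS: dict[str, dict[str, dict[str, int]]] = {
    "default": {
        "sack_yeast": {"fGPAT-A": 2},
        "filamentous_fungus": {"fGPAT-A": 1, "fGPAT-B": 1, "fGDPAT": 1},
        "basal_fungus": {
            "fGPAT-A": 1, "fGPAT-B": 1, "eGPAT": 1, "fGDPAT": 1,
        },
        "vertebrate": {"eGPAT": 2, "mitoGPAT": 1, "DHAPAT": 1},
        "invertebrate": {"eGPAT": 1, "mitoGPAT": 1, "DHAPAT": 1},
        "choanoflagellate": {
            "fGPAT-A": 1, "eGPAT": 1, "mitoGPAT": 1, "DHAPAT": 1,
        },
        "microsporidian": {"eGPAT": 1},
        "decoys_only": {},
    },
    "sack_like": {"sack_yeast": {"fGPAT-A": 2}},
    "single_egpat": {"microsporidian": {"eGPAT": 1}},
}

#: default PTS1 status of planted members: the fungal GDPATs carry a
#: C-terminal peroxisomal targeting signal, as do the peroxisomal DHAPATs
DEFAULT_PTS1 = {"fGDPAT": "canonical", "DHAPAT": "canonical"}


@dataclass
class SurveyScenario:
    """A generated set of proteomes plus everything the survey needs."""

    proteomes: dict[str, dict[str, str]]
    seeds: dict[str, dict[str, str]]
    reference: dict[str, str]
    truth_presence: pd.DataFrame
    truth_members: pd.DataFrame
    plan: dict[str, dict[str, int]] = field(default_factory=dict)


def _founder_protected(
    prof: SubclassProfile, truth_row: pd.Series, seq_len: int,
) -> frozenset[int]:
    """Absolute positions of the motif windows (and the PTS1 tail).

    Orthologue divergence in survey scenarios spares these positions
    entirely: the premise of motif-based detection is that purifying
    selection keeps the catalytic motifs invariant over timescales where
    the rest of the sequence drifts freely.
    """
    protected: set[int] = set()
    for k, label in enumerate(("I", "II", "III", "IV")):
        off = int(truth_row[f"off_{label}"])
        length = int(truth_row[f"len_{label}"])
        protected.update(range(off, off + length))
    # the C-terminal tripeptide is spared whether or not a signal was
    # planted: targeting (and its absence) is treated as a conserved
    # trait of the orthologue set
    protected.update(range(seq_len - 3, seq_len))
    return frozenset(protected)


def generate_survey_set(
    profiles: Mapping[str, SubclassProfile],
    preset: str | dict[str, dict[str, int]] = "default",
    n_per_proteome: int = 300,
    divergence: float = 0.05,
    seed: int = 17,
    decoy_length_range: tuple[int, int] = (150, 600),
    n_reference_decoys: int = 150,
    background: str = "uniform",
) -> SurveyScenario:
    """Generate a directory-shaped survey scenario with known truth.

    Each proteome consists of planted orthologues (one founder per
    subclass, mutated to the requested divergence with diagnostic
    positions spared) padded with decoys to ``n_per_proteome``.  The
    reference proteome holds the founders — the survey's seed queries —
    plus decoys.
    """
    plan = PRESET_PLANS[preset] if isinstance(preset, str) else preset
    if not plan:
        raise ValueError("empty proteome plan")
    used = sorted(
        {sub for members in plan.values() for sub in members},
        key=lambda s: SUBCLASS_ORDER.index(s),
    )
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 3]))

    founders: dict[str, str] = {}
    founder_truth: dict[str, pd.Series] = {}
    seeds_map: dict[str, dict[str, str]] = {}
    for idx, sub in enumerate(used):
        spec = FamilySpec(
            subclass=sub, n=1, background=background,
            pts1=DEFAULT_PTS1.get(sub, "none"),
            seed=int(seed) * 1000 + idx,
        )
        records, truth = generate_family(spec, profiles[sub])
        _, founder_seq = records[0]
        founder_id = f"seed_{sub}"
        founders[sub] = founder_seq
        founder_truth[sub] = truth.iloc[0]
        seeds_map[sub] = {founder_id: founder_seq}

    proteomes: dict[str, dict[str, str]] = {}
    member_rows: list[dict[str, object]] = []
    for pname, members in plan.items():
        prots: dict[str, str] = {}
        for sub in sorted(members, key=lambda s: SUBCLASS_ORDER.index(s)):
            for copy in range(members[sub]):
                protected = _founder_protected(
                    profiles[sub], founder_truth[sub], len(founders[sub])
                )
                seq = mutate_sequence(
                    founders[sub], divergence, rng, protect=protected
                )
                pid = f"{pname}_{sub}_{copy}"
                prots[pid] = seq
                member_rows.append({
                    "proteome": pname, "id": pid, "subclass": sub,
                })
        n_decoys = n_per_proteome - len(prots)
        if n_decoys < 0:
            raise ValueError(
                f"proteome {pname!r} plan exceeds n_per_proteome"
            )
        for name, seq in generate_decoys(
            n_decoys, decoy_length_range, background,
            seed=int(rng.integers(0, 2**31)), prefix=f"{pname}_decoy",
        ):
            prots[name] = seq
        proteomes[pname] = prots

    reference: dict[str, str] = {}
    for sub in used:
        reference.update(seeds_map[sub])
    for name, seq in generate_decoys(
        n_reference_decoys, decoy_length_range, background,
        seed=int(rng.integers(0, 2**31)), prefix="ref_decoy",
    ):
        reference[name] = seq

    truth_presence = pd.DataFrame(
        [
            [plan[pname].get(sub, 0) > 0 for pname in plan]
            for sub in used
        ],
        index=used, columns=list(plan),
    )
    return SurveyScenario(
        proteomes=proteomes,
        seeds=seeds_map,
        reference=reference,
        truth_presence=truth_presence,
        truth_members=pd.DataFrame(
            member_rows, columns=["proteome", "id", "subclass"]
        ),
        plan=plan,
    )


def generate_two_step_scenario(
    profiles: Mapping[str, SubclassProfile],
    subclass: str = "fGPAT-B",
    divergence: float = 0.05,
    n_decoys: int = 400,
    decoy_length_range: tuple[int, int] = (200, 500),
    seed: int = 17,
    background: str = "uniform",
) -> tuple[SurveyScenario, dict[str, str]]:
    """A chained-detectability scenario for the iterative survey.

    The target proteome carries two planted members.  ``A`` keeps the
    seed's flanks (mutated at ``divergence``) but its motif residues are
    redrawn from the patterns avoiding the seed's choices wherever the
    pattern permits, so it is detected at iteration 1 through flank
    similarity while contributing fresh motif information to the profile.
    ``B`` copies ``A``'s motifs exactly but has fresh random flanks and
    sits at legal inter-motif spacings as far as the profile intervals
    allow from the seed's, so no single local alignment can chain its
    motif blocks against the seed: ``B`` shares too little with the seed
    for the E-value screen, yet scores maximally against the
    motif-anchored profile once ``A`` has been absorbed, and should be
    recovered in the second iteration.  The default subclass is fGPAT-B
    because its wide motif II-III spacing interval (21-104) gives ``B``
    the most room to move.
    """
    prof = profiles[subclass]
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 4]))
    pts1 = DEFAULT_PTS1.get(subclass, "none")
    spec = FamilySpec(
        subclass=subclass, n=1, background=background, pts1=pts1,
        seed=int(seed) * 1000 + 7,
    )
    records, truth = generate_family(spec, prof)
    _, founder = records[0]
    founder_id = f"seed_{subclass}"
    row = truth.iloc[0]
    labels = ("I", "II", "III", "IV")

    # redraw motif residues, avoiding the founder's where possible
    a_chars = list(founder)
    new_motifs: list[str] = []
    motif_positions: set[int] = set()
    for k, label in enumerate(labels):
        off = int(row[f"off_{label}"])
        length = int(row[f"len_{label}"])
        pattern = prof.motifs[k]
        optional_idx = [
            i for i, p in enumerate(pattern.positions) if p.optional
        ]
        if length == len(pattern):
            cols = list(range(len(pattern)))
        else:
            cols = [i for i in range(len(pattern)) if i not in optional_idx]
        residues = []
        for rel, col in enumerate(cols):
            allowed = sorted(pattern.positions[col].allowed)
            choices = [r for r in allowed if r != founder[off + rel]]
            pool = choices or allowed
            residues.append(pool[rng.integers(0, len(pool))])
        new_motifs.append("".join(residues))
        a_chars[off:off + length] = residues
        motif_positions.update(range(off, off + length))
    if pts1 != "none":
        motif_positions.update(range(len(founder) - 3, len(founder)))
    member_a = mutate_sequence(
        "".join(a_chars), divergence, rng, protect=frozenset(motif_positions)
    )

    # B: fresh flanks, A's motifs, in-range spacings far from the seed's
    draw_bg = _bg_sampler(background)
    dbms = []
    for k, (lo, hi) in enumerate(prof.dbm_ranges):
        founder_dbm = int(row[f"dbm_{k + 1}"])
        dbms.append(lo if founder_dbm > (lo + hi) // 2 else hi)
    tail = _sample_pts1(pts1, rng) if pts1 != "none" else ""
    core = sum(len(m) for m in new_motifs) + sum(dbms) + len(tail)
    total = int(rng.integers(max(420, core), 651))
    n_flank = int(rng.integers(0, total - core + 1))
    parts = [draw_bg(rng, n_flank)]
    for k, motif in enumerate(new_motifs):
        parts.append(motif)
        if k < 3:
            parts.append(draw_bg(rng, dbms[k]))
    parts.append(draw_bg(rng, total - core - n_flank))
    parts.append(tail)
    member_b = "".join(parts)

    proteome: dict[str, str] = {
        "target_A": member_a,
        "target_B": member_b,
    }
    for name, seq in generate_decoys(
        n_decoys, decoy_length_range, background,
        seed=int(rng.integers(0, 2**31)), prefix="target_decoy",
    ):
        proteome[name] = seq

    scenario = SurveyScenario(
        proteomes={"target": proteome},
        seeds={subclass: {founder_id: founder}},
        reference={founder_id: founder},
        truth_presence=pd.DataFrame(
            [[True]], index=[subclass], columns=["target"]
        ),
        truth_members=pd.DataFrame(
            [
                {"proteome": "target", "id": "target_A",
                 "subclass": subclass},
                {"proteome": "target", "id": "target_B",
                 "subclass": subclass},
            ]
        ),
        plan={"target": {subclass: 2}},
    )
    return scenario, {"A": "target_A", "B": "target_B"}
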