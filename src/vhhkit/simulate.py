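"""Synthetic camelid VHH repertoire generator with known ground truth.

Every pipeline stage is testable without touching the source databases:
records are sampled from per-species generative profiles whose parameters
are the published repertoire summaries — near-fixed framework lengths
(~25/17/38/11 residues for FR1–FR4), species-specific CDR length laws
(rounded normals, e.g. alpaca CDR3 15.2 ± 4.4 aa), conserved framework
consensus strings carrying the canonical FR1/FR3 cysteines, the conserved
FR2 tryptophan and the FR4 W-G-x-G motif, low per-position substitution
noise, lysine enrichment in FR3 (secondarily FR2), and species-dependent
non-canonical cysteines (≈80% of Bactrian/dromedary CDRs, ≈10% of llama
CDRs, ≈40% of alpaca FR2).

The generator also exposes the *analytic expectations* of its own laws
(expected region lengths, residue frequencies, cysteine presence), so
parameter-recovery tests compare pipeline estimates against closed-form
generating values, never against re-simulated numbers.

Deliberate simplifications: CDR residues are drawn i.i.d. from a loop-biased
weight table that excludes Cys and Trp (Cys enters only through the explicit
non-canonical mechanism; Trp is reserved as an annotation anchor), and a
non-canonical cysteine *replaces* one sampled position rather than
lengthening the loop, so length laws stay exact.  Substitution noise never
touches anchor residues.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import norm

from .dataset import (
    CANONICAL_AA,
    Dataset,
    REGIONS,
    SPECIES_ALPACA,
    SPECIES_BACTRIAN,
    SPECIES_DROMEDARY,
    SPECIES_LLAMA,
    ensure_canonical_columns,
)

#: Residues never produced by background sampling: Cys only enters through
#: the explicit non-canonical mechanism, Trp anchors FR2/FR4 delineation.
RESERVED_RESIDUES = frozenset("CW")
BACKGROUND_ALPHABET = [a for a in CANONICAL_AA if a not in RESERVED_RESIDUES]

#: Loop-biased CDR composition weights (normalized at use); Gly/Ser/Tyr-rich
#: as in antigen-binding loops.
DEFAULT_CDR_WEIGHTS = {
    "G": 0.15, "S": 0.13, "Y": 0.10, "A": 0.09, "T": 0.08, "D": 0.08,
    "R": 0.07, "N": 0.06, "V": 0.05, "L": 0.04, "I": 0.04, "P": 0.04,
    "E": 0.03, "K": 0.03, "Q": 0.03, "F": 0.03, "H": 0.02, "M": 0.02,
}


class RoundedNormalLaw:
    """Discrete region-length law: round a normal draw, clamp at a floor.

    The law of ``max(floor, round(Normal(mu, sigma)))``; ``pmf``/``mean``/
    ``sd`` are exact (Gaussian cell probabilities), so recovery tests can
    target the true generating moments rather than the nominal ``mu``.
    """

    def __init__(self, mu: float, sigma: float, floor: int = 3):
        self.mu = float(mu)
        self.sigma = float(sigma)
        self.floor = int(floor)

    def sample(self, rng: np.random.Generator, size: int | None = None):
        draws = np.rint(rng.normal(self.mu, self.sigma, size=size))
        return np.maximum(draws, self.floor).astype(int)

    def support(self) -> np.ndarray:
        hi = int(np.ceil(self.mu + 10 * self.sigma))
        return np.arange(self.floor, hi + 1)

    def pmf(self) -> tuple[np.ndarray, np.ndarray]:
        ks = self.support()
        upper = norm.cdf((ks + 0.5 - self.mu) / self.sigma)
        lower = norm.cdf((ks - 0.5 - self.mu) / self.sigma)
        p = upper - lower
        p[0] = upper[0]  # clamp: all mass below floor collapses onto it
        return ks, p

    def mean(self) -> float:
        ks, p = self.pmf()
        return float((ks * p).sum())

    def sd(self) -> float:
        ks, p = self.pmf()
        m = (ks * p).sum()
        return float(np.sqrt(((ks - m) ** 2 * p).sum()))


class FixedLaw:
    """Degenerate length law for the near-fixed framework regions."""

    def __init__(self, value: int):
        self.value = int(value)

    def sample(self, rng, size=None):
        if size is None:
            return self.value
        return np.full(size, self.value, dtype=int)

    def mean(self) -> float:
        return float(self.value)

    def sd(self) -> float:
        return 0.0


@dataclass
class SpeciesProfile:
    """Generative parameters for one species."""

    species: str
    cdr_length_laws: dict[str, RoundedNormalLaw]
    framework_consensus: dict[str, str]
    framework_substitution_rate: float = 0.02
    cdr_weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CDR_WEIGHTS))
    fr3_lysine_weight: float = 3.0
    fr2_lysine_weight: float = 2.0
    noncanonical_cys_prob: dict[str, float] = field(
        default_factory=lambda: {"CDR1": 0.0, "CDR3": 0.0, "FR2": 0.0}
    )
    fr2_cys_position: int = 12  # 0-based offset of the FR2 non-canonical Cys

    def __post_init__(self):
        for fr, cons in self.framework_consensus.items():
            if fr in ("FR1", "FR3") and "C" not in cons:
                raise ValueError(f"{fr} consensus lacks its canonical cysteine")
        for p in self.noncanonical_cys_prob.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError("cysteine probabilities must be in [0, 1]")
        if any(w < 0 for w in self.cdr_weights.values()) or sum(self.cdr_weights.values()) <= 0:
            raise ValueError("CDR weights must be non-negative and normalizable")

    # -- derived structure -------------------------------------------------

    def protected_positions(self, fr: str) -> set[int]:
        """Anchor positions never touched by substitution noise."""
        cons = self.framework_consensus[fr]
        if fr == "FR1":
            return {cons.index("C")}
        if fr == "FR2":
            return {0}  # conserved Trp
        if fr == "FR3":
            return {len(cons) - 1 - cons[::-1].index("C")}
        return {0, 1, 2, 3}  # FR4 W-G-x-G

    def _background(self, fr: str, exclude: str) -> tuple[list[str], np.ndarray]:
        letters = [a for a in BACKGROUND_ALPHABET if a != exclude]
        w = np.ones(len(letters))
        boost = {"FR2": self.fr2_lysine_weight, "FR3": self.fr3_lysine_weight}.get(fr, 1.0)
        for i, a in enumerate(letters):
            if a == "K":
                w[i] *= boost
        return letters, w / w.sum()

    def _cdr_letters_probs(self) -> tuple[list[str], np.ndarray]:
        letters = [a for a in self.cdr_weights if a not in RESERVED_RESIDUES]
        w = np.array([self.cdr_weights[a] for a in letters], dtype=float)
        return letters, w / w.sum()

    # -- sampling ----------------------------------------------------------

    def sample_framework(self, fr: str, rng: np.random.Generator) -> str:
        cons = list(self.framework_consensus[fr])
        protected = self.protected_positions(fr)
        rate = self.framework_substitution_rate
        if rate > 0:
            for i in range(len(cons)):
                if i in protected:
                    continue
                if rng.random() < rate:
                    letters, probs = self._background(fr, exclude=cons[i])
                    cons[i] = letters[rng.choice(len(letters), p=probs)]
        if fr == "FR2":
            p = self.noncanonical_cys_prob.get("FR2", 0.0)
            if p > 0 and rng.random() < p:
                cons[self.fr2_cys_position] = "C"
        return "".join(cons)

    def sample_cdr(self, cdr: str, rng: np.random.Generator) -> tuple[str, int | None]:
        """Sample one CDR; returns (string, position of non-canonical Cys or None)."""
        length = int(self.cdr_length_laws[cdr].sample(rng))
        letters, probs = self._cdr_letters_probs()
        idx = rng.choice(len(letters), size=length, p=probs)
        residues = [letters[i] for i in idx]
        cys_at = None
        p = self.noncanonical_cys_prob.get(cdr, 0.0)
        if p > 0 and rng.random() < p:
            cys_at = int(rng.integers(0, length))
            residues[cys_at] = "C"
        return "".join(residues), cys_at

    # -- analytic expectations --------------------------------------------

    def expected_region_length(self, region: str) -> float:
        if region in self.cdr_length_laws:
            return self.cdr_length_laws[region].mean()
        return float(len(self.framework_consensus[region]))

    def expected_full_length(self) -> float:
        return sum(self.expected_region_length(r) for r in REGIONS)

    def expected_cys_presence(self, region: str) -> float:
        """Probability that a region carries at least one cysteine."""
        if region in ("FR1", "FR3"):
            return 1.0
        if region == "FR2":
            return self.noncanonical_cys_prob.get("FR2", 0.0)
        if region == "FR4":
            return 0.0
        return self.noncanonical_cys_prob.get(region, 0.0)

    def _framework_position_freq(self, fr: str, pos: int, residue: str) -> float:
        """P(residue at this framework position) under noise + FR2 Cys."""
        cons = self.framework_consensus[fr]
        rate = self.framework_substitution_rate
        if pos in self.protected_positions(fr):
            base = 1.0 if cons[pos] == residue else 0.0
        else:
            letters, probs = self._background(fr, exclude=cons[pos])
            bg = probs[letters.index(residue)] if residue in letters else 0.0
            base = (1.0 - rate) * (1.0 if cons[pos] == residue else 0.0) + rate * bg
        if fr == "FR2" and pos == self.fr2_cys_position:
            p = self.noncanonical_cys_prob.get("FR2", 0.0)
            base = p * (1.0 if residue == "C" else 0.0) + (1.0 - p) * base
        return base

    def expected_region_residue_frequency(self, region: str, residue: str) -> float:
        """Expected pooled frequency of *residue* within *region* (Σn / ΣL)."""
        if region in self.framework_consensus:
            cons = self.framework_consensus[region]
            total = sum(self._framework_position_freq(region, i, residue) for i in range(len(cons)))
            return total / len(cons)
        letters, probs = self._cdr_letters_probs()
        w = probs[letters.index(residue)] if residue in letters else 0.0
        p = self.noncanonical_cys_prob.get(region, 0.0)
        el = self.cdr_length_laws[region].mean()
        # one uniformly chosen position is overwritten by C w.p. p
        expected_count = el * w - p * w + (p if residue == "C" else 0.0)
        return expected_count / el

    def expected_framework_conservation(self, fr: str) -> float:
        """Expected mean per-column consensus frequency of one framework."""
        cons = self.framework_consensus[fr]
        per_col = []
        for i in range(len(cons)):
            per_col.append(self._framework_position_freq(fr, i, cons[i]))
        return float(np.mean(per_col))


def load_framework_consensus() -> dict[str, dict[str, str]]:
    """Framework consensus strings shipped with the package, per species."""
    text = resources.files("vhhkit.data").joinpath("framework_consensus.tsv").read_text()
    lines = [ln.split("\t") for ln in text.strip().splitlines()]
    header = lines[0]
    out = {}
    for row in lines[1:]:
        rec = dict(zip(header, row))
        out[rec["species"]] = {fr: rec[fr] for fr in ("FR1", "FR2", "FR3", "FR4")}
    return out


#: CDR length means/SDs per species: (CDR1, CDR2, CDR3) as (mean, sd).
PUBLISHED_CDR_LAWS = {
    SPECIES_ALPACA: {"CDR1": (8.4, 1.4), "CDR2": (7.9, 1.1), "CDR3": (15.2, 4.4)},
    SPECIES_BACTRIAN: {"CDR1": (7.8, 1.0), "CDR2": (8.0, 1.0), "CDR3": (17.2, 4.3)},
    SPECIES_DROMEDARY: {"CDR1": (7.8, 1.1), "CDR2": (7.8, 0.7), "CDR3": (16.1, 4.3)},
    SPECIES_LLAMA: {"CDR1": (8.8, 2.1), "CDR2": (8.2, 1.3), "CDR3": (16.0, 4.3)},
}

#: Non-canonical cysteine probabilities per species and region.
PUBLISHED_CYS_PROBS = {
    SPECIES_ALPACA: {"CDR1": 0.0, "CDR3": 0.0, "FR2": 0.4},
    SPECIES_BACTRIAN: {"CDR1": 0.8, "CDR3": 0.8, "FR2": 0.0},
    SPECIES_DROMEDARY: {"CDR1": 0.8, "CDR3": 0.8, "FR2": 0.0},
    SPECIES_LLAMA: {"CDR1": 0.1, "CDR3": 0.1, "FR2": 0.0},
}

#: Species counts of the reference census.
PUBLISHED_CENSUS = {
    SPECIES_ALPACA: 325,
    SPECIES_BACTRIAN: 35,
    SPECIES_DROMEDARY: 377,
    SPECIES_LLAMA: 1316,
}


def default_species_profiles(
    substitution_rate: float = 0.02, noncanonical_cys: bool = True
) -> dict[str, SpeciesProfile]:
    """The four default per-species profiles (published summaries as targets)."""
    frameworks = load_framework_consensus()
    profiles = {}
    for sp, laws in PUBLISHED_CDR_LAWS.items():
        profiles[sp] = SpeciesProfile(
            species=sp,
            cdr_length_laws={c: RoundedNormalLaw(m, s) for c, (m, s) in laws.items()},
            framework_consensus=frameworks[sp],
            framework_substitution_rate=substitution_rate,
            noncanonical_cys_prob=dict(PUBLISHED_CYS_PROBS[sp]) if noncanonical_cys
            else {"CDR1": 0.0, "CDR3": 0.0, "FR2": 0.0},
        )
    return profiles


def noise_free_profiles() -> dict[str, SpeciesProfile]:
    """Profiles with zero substitution noise and no non-canonical cysteines."""
    return default_species_profiles(substitution_rate=0.0, noncanonical_cys=False)


@dataclass
class GeneratorConfig:
    """Reproducible repertoire recipe: same seed + config → identical output."""

    seed: int = 20251125
    n_per_species: dict[str, int] = field(default_factory=lambda: dict(PUBLISHED_CENSUS))
    duplicate_rate: float = 0.02
    n_alphabetical: int = 2
    n_homopolymer: int = 2
    profiles: dict[str, SpeciesProfile] | None = None


@dataclass
class TruthManifest:
    """Ground truth of one generated repertoire."""

    records: dict[str, dict] = field(default_factory=dict)
    species_params: dict[str, dict] = field(default_factory=dict)
    duplicates: list[dict] = field(default_factory=list)
    artifacts: list[dict] = field(default_factory=list)

    def n_clean(self) -> int:
        return len(self.records)

    def to_json(self) -> str:
        return json.dumps(
            {
                "records": self.records,
                "species_params": self.species_params,
                "duplicates": self.duplicates,
                "artifacts": self.artifacts,
            },
            indent=1,
        )


def generate_record(
    profile: SpeciesProfile, rng: np.random.Generator, record_id: str, source_db: str = "synthetic"
) -> tuple[dict, dict]:
    """Sample one record; returns (canonical row dict, truth entry)."""
    parts = {}
    cys_insertions = {}
    for region in REGIONS:
        if region in profile.framework_consensus:
            parts[region] = profile.sample_framework(region, rng)
            if region == "FR2" and "C" in parts[region] and "C" not in profile.framework_consensus["FR2"]:
                cys_insertions["FR2"] = profile.fr2_cys_position
        else:
            parts[region], cys_at = profile.sample_cdr(region, rng)
            if cys_at is not None:
                cys_insertions[region] = cys_at
    full = "".join(parts[r] for r in REGIONS)
    row = {
        "record_id": record_id,
        "source_db": source_db,
        "species": profile.species,
        "full_sequence": full,
        **parts,
        "flags": pd.NA,
    }
    boundaries, pos = [], 0
    for r in REGIONS:
        boundaries.append([pos, pos + len(parts[r])])
        pos += len(parts[r])
    truth = {
        "species": profile.species,
        "regions": dict(parts),
        "boundaries": boundaries,
        "cys_insertions": cys_insertions,
    }
    return row, truth


def _alphabetical_decoy(rng: np.random.Generator, length: int = 122) -> str:
    letters = rng.choice(list(CANONICAL_AA), size=length)
    return "".join(sorted(letters))


def _homopolymer_decoy(rng: np.random.Generator, length: int = 120) -> str:
    return rng.choice(list("AG")) * length


def _decoy_regions(seq: str) -> dict[str, str]:
    """Split a decoy into seven deposited-style chunks (artifact mimicry)."""
    cuts, pos = [], 0
    for frac in (25, 8, 17, 8, 38, 15):
        cuts.append(seq[pos : pos + frac])
        pos += frac
    cuts.append(seq[pos:])
    return dict(zip(REGIONS, cuts))


def generate_repertoire(config: GeneratorConfig | None = None) -> tuple[Dataset, TruthManifest]:
    """Generate a full synthetic repertoire with duplicates and decoys.

    Deterministic for a given config: one RNG stream seeded from
    ``config.seed`` drives all sampling.  Duplicate copies (full-sequence
    clones under a fresh identifier) and artificial decoy records are
    appended after the clean cohort and listed in the manifest.
    """
    config = config or GeneratorConfig()
    profiles = config.profiles or default_species_profiles()
    rng = np.random.default_rng(config.seed)
    manifest = TruthManifest()
    rows: list[dict] = []

    species_order = [sp for sp in PUBLISHED_CENSUS if sp in config.n_per_species]
    species_order += [sp for sp in config.n_per_species if sp not in species_order]
    prefix = {SPECIES_ALPACA: "VP", SPECIES_BACTRIAN: "CB", SPECIES_DROMEDARY: "CD", SPECIES_LLAMA: "LG"}
    for sp in species_order:
        profile = profiles[sp]
        n = config.n_per_species[sp]
        for i in range(n):
            rid = f"{prefix.get(sp, 'XX')}{i:05d}"
            row, truth = generate_record(profile, rng, rid)
            rows.append(row)
            manifest.records[rid] = truth
        manifest.species_params[sp] = {
            "n": n,
            "cdr_length_mean": {c: profile.cdr_length_laws[c].mean() for c in ("CDR1", "CDR2", "CDR3")},
            "cdr_length_sd": {c: profile.cdr_length_laws[c].sd() for c in ("CDR1", "CDR2", "CDR3")},
            "framework_substitution_rate": profile.framework_substitution_rate,
            "framework_conservation": {
                fr: profile.expected_framework_conservation(fr) for fr in ("FR1", "FR2", "FR3", "FR4")
            },
            "cys_presence": {r: profile.expected_cys_presence(r) for r in REGIONS},
            "lysine_frequency": {r: profile.expected_region_residue_frequency(r, "K") for r in REGIONS},
            "expected_full_length": profile.expected_full_length(),
        }

    # duplicates: clone already-emitted clean records under new identifiers
    n_dups = int(round(config.duplicate_rate * len(rows)))
    if n_dups > 0:
        chosen = rng.choice(len(rows), size=n_dups, replace=False)
        for j in sorted(int(c) for c in chosen):
            clone = dict(rows[j])
            clone["record_id"] = rows[j]["record_id"] + "_dup"
            rows.append(clone)
            manifest.duplicates.append(
                {"record_id": clone["record_id"], "duplicate_of": rows[j]["record_id"]}
            )

    # artificial decoys, deposited-style (with bogus region strings)
    for k in range(config.n_alphabetical):
        seq = _alphabetical_decoy(rng)
        rid = f"ART_ALPHA{k:03d}"
        rows.append({"record_id": rid, "source_db": "synthetic", "species": SPECIES_LLAMA,
                     "full_sequence": seq, **_decoy_regions(seq), "flags": pd.NA})
        manifest.artifacts.append({"record_id": rid, "rule": "alphabetical_order"})
    for k in range(config.n_homopolymer):
        seq = _homopolymer_decoy(rng, length=118 + 2 * k)
        rid = f"ART_HOMO{k:03d}"
        rows.append({"record_id": rid, "source_db": "synthetic", "species": SPECIES_LLAMA,
                     "full_sequence": seq, **_decoy_regions(seq), "flags": pd.NA})
        manifest.artifacts.append({"record_id": rid, "rule": "homopolymer_low_complexity"})

    df = ensure_canonical_columns(pd.DataFrame(rows))
    ds = Dataset(df)
    ds.log("simulate", len(df), 0)
    return ds, manifest
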