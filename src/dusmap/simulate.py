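"""Seeded generators for every input the pipeline consumes, with ground truth.

The generators emulate the study design around a two-enzyme (B1/B2)
dihydrouridine synthase system assayed across a four-strain knockout panel
(WT, single deletions, double deletion):

* tRNA-like substrates (~76 nt) whose designated canonical sites (17, 20,
  20a, 47, ...) carry U inside guanosine-flanked contexts so that RNase T1
  digestion yields a small single-candidate diagnostic fragment per site;
* MALDI peak lists per purified tRNA and strain, with the modified/unmodified
  intensity split set by the genotype-dependent stoichiometry, Gaussian m/z
  jitter and log-normal intensity noise;
* aniline-cleavage read-start count profiles: Poisson background everywhere
  plus a binomial cleavage spike at the N+1 read start of each modified site
  (the offset is built in, so scoring must undo it);
* Michaelis-Menten rate series with multiplicative noise.

Every generator is a pure function of (parameters, seed).  Modification
stoichiometries default to the sub-stoichiometric 0.3-0.9 range, since
in-cell dihydrouridine is not found at full occupancy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .cleavage import CleavageProfile
from .digestion import digest, RNASE_T1
from .maldi import Peak, PeakList, PREFERENCE_MARGIN, STRAINS
from .masses import MassSpec, fragment_mass
from .kinetics import RateSeries
from .trna import AnnotatedTRNA, PositionLabel, TRNAError

__all__ = [
    "NoiseConfig", "EnzymeSpecificityMap", "ENZYMES", "GENOTYPE_DELETIONS",
    "gen_trna_set", "gen_maldi_panel", "gen_cleavage_profiles", "gen_kinetics",
    "DEFAULT_SITE_PROFILE",
]

ENZYMES = ("B1", "B2")

GENOTYPE_DELETIONS = {
    "WT": frozenset(),
    "dB1": frozenset({"B1"}),
    "dB2": frozenset({"B2"}),
    "dB1dB2": frozenset({"B1", "B2"}),
}

# Stoichiometry range for enzyme efficiencies drawn by the generator:
# in-cell D sites are partially modified.
EFF_RANGE = (0.3, 0.9)

#: Canonical D-site inventory with a typical redundancy structure: 17 and 47
#: served by B1 alone, the 20/20a cluster by both enzymes.  ``None`` means
#: "draw the efficiency from EFF_RANGE".
DEFAULT_SITE_PROFILE: dict[str, dict[str, float | None]] = {
    "17": {"B1": None},
    "20": {"B1": None, "B2": None},
    "20a": {"B1": None, "B2": None},
    "47": {"B1": None},
}


@dataclass(frozen=True)
class NoiseConfig:
    mz_jitter_sd: float = 0.05       # Da
    intensity_cv: float = 0.2        # log-normal CV on peak intensities
    background_lambda: float = 5.0   # mean background read-start counts
    coverage: int = 1000             # reads traversing each position
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.mz_jitter_sd, self.intensity_cv,
               self.background_lambda) < 0 or self.coverage < 0:
            raise ValueError("noise parameters must be nonnegative")


#: Noise-free configuration: deterministic peaks, flat-zero backgrounds.
ZERO_NOISE = NoiseConfig(mz_jitter_sd=0.0, intensity_cv=0.0,
                         background_lambda=0.0)


class EnzymeSpecificityMap:
    """Ground truth: which enzyme(s) serve each site, at what efficiency."""

    def __init__(self) -> None:
        self._sites: dict[tuple[str, str], dict[str, float]] = {}

    def add(self, trna_id: str, label: PositionLabel | str,
            efficiencies: Mapping[str, float]) -> None:
        for enz, eff in efficiencies.items():
            if enz not in ENZYMES:
                raise TRNAError(f"unknown enzyme {enz!r}")
            if not 0 < eff <= 1:
                raise TRNAError(f"efficiency must be in (0, 1], got {eff}")
        self._sites[(trna_id, str(label))] = dict(efficiencies)

    def sites(self, trna_id: str) -> dict[str, dict[str, float]]:
        return {label: effs for (tid, label), effs in self._sites.items()
                if tid == trna_id}

    def items(self):
        return self._sites.items()

    def __len__(self) -> int:
        return len(self._sites)

    def stoichiometry(self, trna_id: str, label: PositionLabel | str,
                      genotype: str) -> float:
        """Modified fraction at a site in a given strain: 1 - prod(1 - eff)."""
        deleted = GENOTYPE_DELETIONS[genotype]
        effs = self._sites.get((trna_id, str(label)), {})
        p = 1.0
        for enz, eff in effs.items():
            if enz not in deleted:
                p *= 1.0 - eff
        return 1.0 - p

    def expected_attribution(self, trna_id: str, label: PositionLabel | str,
                             margin: float = PREFERENCE_MARGIN) -> str:
        """The attribution the analysis should recover at zero noise."""
        effs = self._sites.get((trna_id, str(label)), {})
        present = {e: v for e, v in effs.items() if v > 0}
        if not present:
            return "none"
        if set(present) == {"B1"}:
            return "B1_only"
        if set(present) == {"B2"}:
            return "B2_only"
        e1, e2 = present["B1"], present["B2"]
        # the single-knockout modified fraction equals the OTHER enzyme's
        # efficiency, so preference follows the efficiency gap
        if e1 <= e2 - margin:
            return "redundant_B2_preferred"
        if e2 <= e1 - margin:
            return "redundant_B1_preferred"
        return "redundant"


# ---------------------------------------------------------------------------
# tRNA substrates

_TRNA_LENGTH = 76
# Per-site diagnostic context prefixes (the residues between the 5' flanking
# G and the site's U).  Compositions are pairwise distinct so that the
# diagnostic fragments of co-occurring sites never share a mass.
_SITE_PREFIX = {"16": "AA", "17": "AC", "20": "C", "20a": "A",
                "20b": "CC", "47": "ACC"}
_FALLBACK_PREFIXES = ("CAA", "CCA", "AAA", "CCC", "ACA", "CAC")


def _site_indices(labels: Sequence[PositionLabel],
                  chosen: Sequence[PositionLabel]) -> dict[PositionLabel, int]:
    index = {lab: i for i, lab in enumerate(labels)}
    return {lab: index[lab] for lab in chosen}


def _select_sites(profile: Mapping[str, Mapping[str, float | None]],
                  rng: np.random.Generator) -> list[PositionLabel]:
    """One site per adjacency cluster (e.g. pick 20 or 20a, not both)."""
    labels = sorted(PositionLabel.parse(s) for s in profile)
    clusters: list[list[PositionLabel]] = []
    for lab in labels:
        if clusters and _labels_adjacent(clusters[-1][-1], lab):
            clusters[-1].append(lab)
        else:
            clusters.append([lab])
    return sorted(c[int(rng.integers(len(c)))] for c in clusters)


def _labels_adjacent(a: PositionLabel, b: PositionLabel) -> bool:
    # consecutive canonical positions, counting insertion letters
    if a.number == b.number:
        return True
    if b.number == a.number + 1 and not b.suffix:
        return True
    return False


def gen_trna_set(n: int, seed: int,
                 site_profile: Mapping[str, Mapping[str, float | None]] | None = None,
                 ) -> tuple[list[AnnotatedTRNA], EnzymeSpecificityMap]:
    """Generate tRNA-like substrates with diagnosable D sites and ground truth.

    ``site_profile`` maps a canonical label to {enzyme: efficiency}; a ``None``
    efficiency is drawn uniformly from the sub-stoichiometric default range.
    Each tRNA receives one site per adjacency cluster of the profile (adjacent
    candidate U's cannot be monitored separately by digestion).
    """
    if n < 1:
        raise TRNAError("n must be >= 1")
    profile = dict(site_profile or DEFAULT_SITE_PROFILE)
    rng = np.random.default_rng(seed)

    trnas: list[AnnotatedTRNA] = []
    truth = EnzymeSpecificityMap()
    for t in range(n):
        trna_id = f"syn-tRNA-{t + 1:03d}"
        chosen = _select_sites(profile, rng)

        labels: list[PositionLabel] = []
        for num in range(1, _TRNA_LENGTH + 1):
            labels.append(PositionLabel(num))
            for suffix in "ab":
                lab = PositionLabel(num, suffix)
                if lab in chosen:
                    labels.append(lab)
        idx = _site_indices(labels, chosen)

        letters: list[str | None] = [None] * len(labels)
        used_prefixes: set[str] = set()
        prev_flank = -1
        ok = True
        for k, site in enumerate(chosen):
            i = idx[site]
            prefix = _SITE_PREFIX.get(str(site))
            if prefix is None or "".join(sorted(prefix)) in used_prefixes:
                pool = [p for p in _FALLBACK_PREFIXES
                        if "".join(sorted(p)) not in used_prefixes]
                prefix = pool[0]
            # prefix occupies prev_flank+1 .. i-1 at most; the 5' flanking G
            # may be shared with the previous site's 3' flank
            room = i - prev_flank - 1
            if room < 1 or i + 1 >= len(labels):
                ok = False
                break
            prefix = prefix[:room]
            used_prefixes.add("".join(sorted(prefix)))
            start = i - len(prefix)
            if start - 1 < 0 or letters[start - 1] not in (None, "G"):
                ok = False
                break
            letters[start - 1] = "G"
            for j, ch in enumerate(prefix):
                letters[start + j] = ch
            letters[i] = "U"
            letters[i + 1] = "G"
            prev_flank = i + 1
        if not ok:
            raise TRNAError(
                f"site profile {sorted(profile)} cannot be embedded at "
                f"canonical spacing")

        # filler: A/C only (no stray U candidates, no extra cuts), CCA tail
        for j, ch in enumerate(letters):
            if ch is None:
                letters[j] = "A" if rng.random() < 0.7 else "C"
        letters[-3:] = ["C", "C", "A"]

        mods: dict[str, str] = {}
        effs_by_site: dict[PositionLabel, dict[str, float]] = {}
        for site in chosen:
            effs = {}
            for enz, eff in profile[str(site)].items():
                effs[enz] = float(rng.uniform(*EFF_RANGE)) if eff is None else float(eff)
            effs_by_site[site] = effs
            mods[str(site)] = "D"  # wild-type molecules carry the modification

        trna = AnnotatedTRNA.from_sequence(
            trna_id, "".join(letters), labels=[str(x) for x in labels],
            modifications_at=mods, isoacceptor="synthetic")
        trnas.append(trna)
        for site, effs in effs_by_site.items():
            truth.add(trna_id, site, effs)
    return trnas, truth


# ---------------------------------------------------------------------------
# MALDI strain panels

def gen_maldi_panel(trna: AnnotatedTRNA, truth: EnzymeSpecificityMap,
                    genotype: str, noise: NoiseConfig = NoiseConfig(),
                    enzyme=RNASE_T1, base_intensity: float = 100.0,
                    rng: np.random.Generator | None = None) -> PeakList:
    """Simulated spectrum of one purified tRNA digested in one strain.

    Every complete-digest fragment contributes a peak; fragments holding a
    D site contribute a modified/unmodified pair whose intensity split is the
    genotype-dependent stoichiometry.  With the double deletion the modified
    member vanishes entirely.
    """
    if genotype not in GENOTYPE_DELETIONS:
        raise TRNAError(f"unknown genotype {genotype!r}")
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    spec = MassSpec()  # monoisotopic [M+H]+, exact
    site_labels = set(truth.sites(trna.id))

    def jitter(mz: float) -> float:
        return mz + (rng.normal(0.0, noise.mz_jitter_sd)
                     if noise.mz_jitter_sd > 0 else 0.0)

    def noisy(i: float) -> float:
        if noise.intensity_cv > 0:
            sigma = np.sqrt(np.log1p(noise.intensity_cv ** 2))
            i *= rng.lognormal(-sigma ** 2 / 2.0, sigma)
        return i

    peaks: list[Peak] = []
    for frag in digest(trna, enzyme):
        frag_sites = [r.label for r in frag.residues
                      if str(r.label) in site_labels]
        base_mass = fragment_mass(_strip_d(frag), spec)
        if not frag_sites:
            peaks.append(Peak(jitter(base_mass), noisy(base_intensity)))
            continue
        # independent sites: enumerate modification states of the fragment
        probs = [truth.stoichiometry(trna.id, lab, genotype)
                 for lab in frag_sites]
        for state in range(1 << len(frag_sites)):
            p = 1.0
            n_mod = 0
            for b, prob in enumerate(probs):
                if state >> b & 1:
                    p *= prob
                    n_mod += 1
                else:
                    p *= 1.0 - prob
            if p <= 0.0:
                continue
            mz = base_mass + n_mod * 2.01565
            peaks.append(Peak(jitter(mz), noisy(base_intensity * p)))
    peaks.sort(key=lambda p: p.mz)
    return PeakList(peaks, strain=genotype)


def _strip_d(fragment):
    from .digestion import Fragment
    from .trna import Residue
    residues = tuple(Residue(r.base, r.label, None) if r.modification == "D"
                     else r for r in fragment.residues)
    return Fragment(residues, fragment.parent_id, fragment.five_prime,
                    fragment.three_prime)


def gen_maldi_strain_panels(trna: AnnotatedTRNA, truth: EnzymeSpecificityMap,
                            noise: NoiseConfig = NoiseConfig(),
                            enzyme=RNASE_T1,
                            rng: np.random.Generator | None = None,
                            ) -> dict[str, PeakList]:
    """All four strains' spectra for one tRNA (shared RNG stream)."""
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    return {g: gen_maldi_panel(trna, truth, g, noise, enzyme=enzyme, rng=rng)
            for g in STRAINS}


# ---------------------------------------------------------------------------
# Cleavage (read-start) profiles

def gen_cleavage_profiles(trnas: Iterable[AnnotatedTRNA],
                          truth: EnzymeSpecificityMap, genotype: str,
                          replicates: int = 1,
                          noise: NoiseConfig = NoiseConfig(),
                          rng: np.random.Generator | None = None,
                          stoichiometry_override: Mapping[tuple[str, str], float] | None = None,
                          ) -> list[CleavageProfile]:
    """Simulated per-position read-start counts for one strain.

    Background read starts are Poisson(background_lambda) at every position;
    the read start one residue 3' of each modified site (N+1) additionally
    receives Binomial(coverage, stoichiometry) cleavage events.
    ``stoichiometry_override`` replaces the genotype stoichiometry per
    (trna_id, label), e.g. for enzyme-titration series.
    """
    if genotype not in GENOTYPE_DELETIONS:
        raise TRNAError(f"unknown genotype {genotype!r}")
    if noise.coverage <= 0:
        raise TRNAError("coverage must be positive")
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    profiles = []
    for rep in range(1, replicates + 1):
        for trna in trnas:
            n = len(trna)
            counts = rng.poisson(noise.background_lambda, size=n).astype(np.int64)
            coverage = np.full(n, noise.coverage, dtype=np.int64)
            for label in truth.sites(trna.id):
                p = truth.stoichiometry(trna.id, label, genotype)
                if stoichiometry_override is not None:
                    p = stoichiometry_override.get((trna.id, label), p)
                i = trna.label_to_index(label)
                if i + 1 < n and p > 0:
                    counts[i + 1] += rng.binomial(noise.coverage, p)
            np.minimum(counts, coverage, out=counts)
            profiles.append(CleavageProfile(trna.id, counts, coverage,
                                            sample=genotype, replicate=rep))
    return profiles


# ---------------------------------------------------------------------------
# Kinetics

def gen_kinetics(kcat: float, km: float, enzyme_conc: float,
                 conc_grid: Sequence[float], cv: float = 0.0,
                 seed: int = 0, substrate_name: str = "") -> RateSeries:
    """Michaelis-Menten rate series with multiplicative Gaussian noise."""
    s = np.asarray(conc_grid, dtype=float)
    if s.min() >= km or s.max() <= km:
        raise TRNAError("concentration grid must span KM")
    rng = np.random.default_rng(seed)
    v = kcat * enzyme_conc * s / (km + s)
    if cv > 0:
        v = v * (1.0 + cv * rng.standard_normal(len(s)))
    return RateSeries(s, v, enzyme_conc=enzyme_conc,
                      substrate_name=substrate_name)
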