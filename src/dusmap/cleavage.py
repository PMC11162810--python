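"""Per-position cleavage scoring of aniline-sequencing count tables.

Alkaline treatment opens the dihydrouridine ring; aniline then cleaves the
backbone, leaving a 5'-phosphate on the residue one position 3' of the
modified base (the N+1 convention).  Sequencing read starts therefore report
the residue 5' of them, and this module undoes that offset internally: all
scores are in residue coordinates.

Two statistics per position:

* ``normcount`` — the cleavage count attributed to a residue divided by the
  median background cleavage over the surrounding 10 nucleotides (5 nearest
  flanks per side, truncated at molecule ends; the median is floored at 1
  count to stay defined over dead background).  Sensitive but not linear in
  modification level.
* ``stop_ratio`` — attributed count over traversing coverage: a direct
  (if noisy) stoichiometry proxy in [0, 1].

The same base-lability chemistry co-detects m7G, m3C and ho5C; high scores at
non-U residues are therefore reported in a separate channel, never suppressed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .maldi import SitePanel, SiteState, STRAINS, decide_attribution, site_state
from .trna import AnnotatedTRNA, PositionLabel, TRNAError

__all__ = [
    "CleavageProfile", "CleavageScore", "normcount", "stop_ratio",
    "call_sites", "SiteCalls", "heatmap_matrix", "dose_response",
    "DoseResponse", "panel_attribution_from_seq", "read_count_table",
    "DEFAULT_SCORE_THRESHOLD", "DEFAULT_WINDOW",
]

DEFAULT_WINDOW = 10       # flanking positions pooled for the background median
DEFAULT_SCORE_THRESHOLD = 5.0


@dataclass
class CleavageProfile:
    """Read-start counts and coverage along one tRNA in one sample."""

    trna_id: str
    counts: np.ndarray
    coverage: np.ndarray
    sample: str = ""
    replicate: int = 1

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.coverage = np.asarray(self.coverage, dtype=np.int64)
        if self.counts.shape != self.coverage.shape or self.counts.ndim != 1:
            raise TRNAError("counts and coverage must be equal-length vectors")
        if (self.counts < 0).any() or (self.coverage < 0).any():
            raise TRNAError("counts and coverage must be nonnegative")
        if (self.counts > self.coverage).any():
            raise TRNAError("read-start counts cannot exceed coverage")

    def __len__(self) -> int:
        return len(self.counts)

    def attributed_counts(self) -> np.ndarray:
        """Counts re-indexed to the residue that caused the cleavage (N+1 undo).

        The last residue has no downstream read start and gets 0.
        """
        att = np.zeros_like(self.counts)
        att[:-1] = self.counts[1:]
        return att


@dataclass(frozen=True)
class CleavageScore:
    site: PositionLabel | int
    normcount: float
    stop_ratio: float | None
    base: str = ""
    substoichiometric: bool = False


def normcount(profile: CleavageProfile, position: int,
              window: int = DEFAULT_WINDOW) -> float:
    """Signal at a residue over the median background of its flanks."""
    n = len(profile)
    if n < 3:
        raise TRNAError("profile too short to score (need >= 3 positions)")
    if not 0 <= position < n:
        raise TRNAError(f"position {position} outside profile of length {n}")
    att = profile.attributed_counts()
    half = window // 2
    left = list(range(max(0, position - half), position))
    right = list(range(position + 1, min(n, position + half + 1)))
    flanks = left + right
    if not flanks:
        raise TRNAError("no flanking positions available")
    background = float(np.median(att[flanks]))
    return float(att[position]) / max(background, 1.0)


def stop_ratio(profile: CleavageProfile, position: int) -> float | None:
    """Attributed counts over coverage at the attributed read start.

    Returns None (undetected) when coverage there is zero — distinct from a
    genuine 0.0, which means covered but never cleaved.
    """
    n = len(profile)
    if not 0 <= position < n:
        raise TRNAError(f"position {position} outside profile of length {n}")
    if position == n - 1:
        return None
    cov = int(profile.coverage[position + 1])
    if cov == 0:
        return None
    return float(profile.counts[position + 1]) / cov


@dataclass
class SiteCalls:
    """Called modification sites, split into the D channel (U residues) and
    the co-detection channel (high signal at non-U residues, e.g. m7G)."""

    d_sites: list[CleavageScore]
    other_sites: list[CleavageScore]


def call_sites(profile: CleavageProfile,
               trna: AnnotatedTRNA | None = None,
               candidate_positions: Iterable[int] | None = None,
               score_threshold: float = DEFAULT_SCORE_THRESHOLD,
               window: int = DEFAULT_WINDOW) -> SiteCalls:
    """Flag positions whose normcount clears the threshold.

    Candidates default to all U residues of ``trna`` (or every position when
    no sequence is supplied).  Non-U positions above threshold are returned
    in the co-detection channel.  Called sites with stop_ratio < 1 carry the
    sub-stoichiometric flag.
    """
    if score_threshold <= 1:
        raise TRNAError("score threshold must exceed 1 (the background level)")
    n = len(profile)
    if trna is not None and len(trna) != n:
        raise TRNAError(
            f"profile length {n} does not match tRNA {trna.id} length {len(trna)}")

    if candidate_positions is None:
        positions = range(n - 1)
    else:
        positions = list(candidate_positions)

    d_sites, other = [], []
    for i in positions:
        score = normcount(profile, i, window)
        if score < score_threshold:
            continue
        sr = stop_ratio(profile, i)
        base = trna.residues[i].base if trna is not None else ""
        label: PositionLabel | int = trna.index_to_label(i) if trna is not None else i
        rec = CleavageScore(label, score, sr, base=base,
                            substoichiometric=(sr is not None and sr < 1.0))
        if trna is None or base == "U":
            d_sites.append(rec)
        else:
            other.append(rec)
    return SiteCalls(d_sites, other)


def heatmap_matrix(profiles: Sequence[CleavageProfile],
                   sites: Mapping[str, Sequence[int]]) -> pd.DataFrame:
    """Site x sample matrix of mean stop_ratio over replicates.

    ``sites`` maps trna_id -> residue positions.  Rows are labelled
    ``trna_id:position``; missing data stays NaN, distinct from 0.0.
    """
    lengths: dict[str, int] = {}
    for p in profiles:
        if lengths.setdefault(p.trna_id, len(p)) != len(p):
            raise TRNAError(f"inconsistent profile lengths for {p.trna_id}")
    cells: dict[tuple[str, str], list[float]] = {}
    samples: list[str] = []
    for p in profiles:
        if p.sample not in samples:
            samples.append(p.sample)
        for pos in sites.get(p.trna_id, ()):
            sr = stop_ratio(p, pos)
            if sr is not None:
                cells.setdefault((f"{p.trna_id}:{pos}", p.sample), []).append(sr)
    rows = [f"{tid}:{pos}" for tid, poss in sites.items() for pos in poss]
    mat = pd.DataFrame(np.nan, index=rows, columns=samples)
    for (row, sample), vals in cells.items():
        mat.loc[row, sample] = float(np.mean(vals))
    return mat


@dataclass
class DoseResponse:
    concentrations: list[float]
    scores: list[float]
    monotone: bool
    flat: bool


def dose_response(profiles: Sequence[CleavageProfile],
                  concentrations: Sequence[float], position: int,
                  window: int = DEFAULT_WINDOW) -> DoseResponse:
    """Normcount along an enzyme-concentration series, with a trend flag.

    ``monotone`` requires perfect rank concordance (Spearman rho = 1) between
    concentration and score; a constant series is monotone but flagged flat.
    """
    if len(profiles) != len(concentrations):
        raise TRNAError("one profile per concentration required")
    if len(profiles) < 3:
        raise TRNAError("dose-response needs at least 3 concentrations")
    order = np.argsort(concentrations)
    concs = [float(concentrations[i]) for i in order]
    scores = [normcount(profiles[i], position, window) for i in order]
    if len(set(scores)) == 1:
        return DoseResponse(concs, scores, monotone=True, flat=True)
    rho = stats.spearmanr(concs, scores).statistic
    return DoseResponse(concs, scores, monotone=bool(rho == 1.0), flat=False)


def panel_attribution_from_seq(strain_ratios: Mapping[str, float | None],
                               site: PositionLabel | int = 0,
                               trna_id: str = "") -> SitePanel:
    """Attribute a site from its per-strain stop ratios.

    Reuses the MALDI grid: a stop ratio is already a modified-fraction
    proxy, so it feeds the same thresholds and decision rules.
    """
    states: dict[str, SiteState] = {}
    for strain in STRAINS:
        if strain not in strain_ratios:
            raise TRNAError(f"missing strain column {strain}")
        sr = strain_ratios[strain]
        if sr is None:
            states[strain] = SiteState(site, trna_id, strain, None, "undetected")
        else:
            # feed the ratio through the shared thresholds as a pseudo pair
            states[strain] = site_state(sr, 1.0 - sr, site=site,
                                        trna_id=trna_id, strain=strain)
    return SitePanel(site, trna_id, states, decide_attribution(states))


def read_count_table(source, sample: str = "", replicate: int = 1,
                     ) -> list[CleavageProfile]:
    """TSV (trna_id, position_index, read_start_count, coverage) -> profiles."""
    df = pd.read_csv(source, sep="\t")
    needed = {"trna_id", "position_index", "read_start_count", "coverage"}
    if not needed <= set(df.columns):
        raise TRNAError(f"count table needs columns {sorted(needed)}")
    profiles = []
    for trna_id, grp in df.groupby("trna_id", sort=False):
        grp = grp.sort_values("position_index")
        n = int(grp["position_index"].max()) + 1
        counts = np.zeros(n, dtype=np.int64)
        coverage = np.zeros(n, dtype=np.int64)
        counts[grp["position_index"].to_numpy()] = grp["read_start_count"].to_numpy()
        coverage[grp["position_index"].to_numpy()] = grp["coverage"].to_numpy()
        profiles.append(CleavageProfile(str(trna_id), counts, coverage,
                                        sample=sample, replicate=replicate))
    return profiles
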