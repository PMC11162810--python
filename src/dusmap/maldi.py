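"""Diagnostic-fragment selection, MALDI peak matching and knockout-panel
enzyme attribution.

The experimental logic being automated: a dihydrouridine site is monitored
through the smallest digest fragment that contains it and only it, whose
modified/unmodified masses sit 2 Da apart and collide with nothing else in
the digest.  Across a wild-type / single-knockout / double-knockout strain
panel, the ratio f = I(mod)/(I(mod)+I(unmod)) per strain tells which enzyme
installs the modification: a site still modified when enzyme B2 is deleted
but lost when B1 is deleted is a B1-only site; a site lost only in the
double mutant is served redundantly by both, with a preference read from
which single deletion depresses f more.

MALDI intensities are treated as relative within one spectrum only; no
cross-spectrum normalization beyond f is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .digestion import Fragment, digest, get_rule
from .masses import MassSpec, fragment_mass
from .trna import (AnnotatedTRNA, ModificationTable, DEFAULT_MODIFICATIONS,
                   PositionLabel, Residue, TRNAError)

__all__ = [
    "Peak", "PeakList", "DiagnosticFragment", "SiteState", "SitePanel",
    "STRAINS", "select_diagnostics", "match_peaks", "site_state",
    "decide_attribution", "attribute_panel", "read_peak_list",
    "panel_report_table",
]

STRAINS = ("WT", "dB1", "dB2", "dB1dB2")

# Call thresholds: fraction-modified >= MODIFIED_MIN -> "modified",
# <= UNMODIFIED_MAX -> "unmodified", in between -> "reduced".  A site is
# "undetected" when the summed pair intensity falls below UNDETECTED_FLOOR_FRAC
# of the spectrum's median peak intensity.  PREFERENCE_MARGIN is the minimum
# difference in single-mutant f to call one enzyme the preferred contributor.
MODIFIED_MIN = 0.8
UNMODIFIED_MAX = 0.1
UNDETECTED_FLOOR_FRAC = 0.05
PREFERENCE_MARGIN = 0.3
DEFAULT_TOLERANCE_DA = 0.5


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("m/z must be positive")
        if self.intensity < 0:
            raise ValueError("intensity must be nonnegative")


@dataclass
class PeakList:
    peaks: list[Peak]
    strain: str = ""

    def __iter__(self):
        return iter(self.peaks)

    def __len__(self) -> int:
        return len(self.peaks)

    def median_intensity(self) -> float:
        if not self.peaks:
            return 0.0
        return float(np.median([p.intensity for p in self.peaks]))


@dataclass(frozen=True)
class DiagnosticFragment:
    """The fragment pair used to monitor one candidate site."""

    fragment: Fragment
    site: PositionLabel
    mz_modified: float
    mz_unmodified: float
    trna_id: str = ""


@dataclass(frozen=True)
class SiteState:
    site: PositionLabel
    trna_id: str
    strain: str
    modified_fraction: float | None   # None = undetected
    call: str                         # modified | reduced | unmodified | undetected


@dataclass
class SitePanel:
    site: PositionLabel
    trna_id: str
    states: dict[str, SiteState]
    attribution: str = field(default="")

    def fraction(self, strain: str) -> float | None:
        return self.states[strain].modified_fraction


def _candidate_labels(trna: AnnotatedTRNA,
                      candidate_sites: Iterable) -> list[PositionLabel]:
    labels = []
    for s in candidate_sites:
        lab = s if isinstance(s, PositionLabel) else PositionLabel.parse(s)
        res = trna.residues[trna.label_to_index(lab)]
        if res.base != "U":
            raise TRNAError(
                f"candidate site {lab} in {trna.id} is {res.base}, not U/D")
        labels.append(lab)
    return labels


def _with_site_state(fragment: Fragment, site: PositionLabel,
                     modified: bool) -> Fragment:
    """Copy of the fragment with D present/absent at the site position."""
    residues = tuple(
        Residue(r.base, r.label, "D" if modified else None)
        if r.label == site else r
        for r in fragment.residues)
    return Fragment(residues, fragment.parent_id,
                    fragment.five_prime, fragment.three_prime)


def select_diagnostics(trna: AnnotatedTRNA, enzyme,
                       candidate_sites: Iterable,
                       tolerance_da: float = DEFAULT_TOLERANCE_DA,
                       spec: MassSpec = MassSpec(),
                       table: ModificationTable = DEFAULT_MODIFICATIONS,
                       ) -> tuple[list[DiagnosticFragment], list[PositionLabel]]:
    """Pick, per candidate site, the smallest unique digest fragment.

    A fragment qualifies when it contains exactly one candidate site and
    neither member of its modified/unmodified mass pair lies within
    ``tolerance_da`` of any other complete-digest fragment mass.  Returns
    (diagnostics, unmonitorable site labels).
    """
    sites = _candidate_labels(trna, candidate_sites)
    frags = digest(trna, get_rule(enzyme))
    frag_masses = [fragment_mass(f, spec, table) for f in frags]

    diagnostics: list[DiagnosticFragment] = []
    unmonitorable: list[PositionLabel] = []
    for site in sites:
        chosen = None
        for frag in sorted((f for f in frags if f.covers(site)), key=len):
            inside = [s for s in sites if frag.covers(s)]
            if len(inside) != 1:
                continue
            mod = fragment_mass(_with_site_state(frag, site, True), spec, table)
            unmod = fragment_mass(_with_site_state(frag, site, False), spec, table)
            others = [m for f, m in zip(frags, frag_masses) if f is not frag]
            if any(abs(m - mod) <= tolerance_da or abs(m - unmod) <= tolerance_da
                   for m in others):
                continue
            chosen = DiagnosticFragment(frag, site, mod, unmod, trna.id)
            break
        if chosen is None:
            unmonitorable.append(site)
        else:
            diagnostics.append(chosen)
    return diagnostics, unmonitorable


def match_peaks(peaks: PeakList, diagnostics: Sequence[DiagnosticFragment],
                tolerance_da: float = DEFAULT_TOLERANCE_DA,
                ) -> dict[DiagnosticFragment, tuple[float, float]]:
    """Sum peak intensity within tolerance of each diagnostic pair member.

    A peak in range of several targets is credited only to the nearest one.
    """
    if tolerance_da <= 0:
        raise ValueError("tolerance must be positive")
    targets: list[tuple[DiagnosticFragment, int, float]] = []
    for d in diagnostics:
        targets.append((d, 0, d.mz_modified))
        targets.append((d, 1, d.mz_unmodified))

    sums: dict[DiagnosticFragment, list[float]] = {d: [0.0, 0.0] for d in diagnostics}
    for peak in peaks:
        best = None
        best_dist = tolerance_da
        for d, which, mz in targets:
            dist = abs(peak.mz - mz)
            if dist <= best_dist:
                best, best_dist = (d, which), dist
        if best is not None:
            sums[best[0]][best[1]] += peak.intensity
    return {d: (v[0], v[1]) for d, v in sums.items()}


def site_state(i_mod: float, i_unmod: float, *, site: PositionLabel | None = None,
               trna_id: str = "", strain: str = "",
               floor: float = 0.0) -> SiteState:
    """Classify one site in one strain from its pair intensities.

    ``floor`` is the minimum summed intensity for the site to count as
    detected (typically 5% of the spectrum's median peak intensity).
    """
    if i_mod < 0 or i_unmod < 0:
        raise ValueError("intensities must be nonnegative")
    total = i_mod + i_unmod
    if total <= floor or total == 0:
        return SiteState(site, trna_id, strain, None, "undetected")
    f = i_mod / total
    if f >= MODIFIED_MIN:
        call = "modified"
    elif f <= UNMODIFIED_MAX:
        call = "unmodified"
    else:
        call = "reduced"
    return SiteState(site, trna_id, strain, f, call)


def decide_attribution(states: Mapping[str, SiteState],
                       preference_margin: float = PREFERENCE_MARGIN) -> str:
    """Assign a site to its enzyme(s) from the four-strain call pattern.

    Rules, in order: (1) WT unmodified -> none; (2) double mutant still
    modified -> inconsistent; (3) detected in the B2 knockout but lost in the
    B1 knockout -> B1_only (and symmetrically); (5) detected in both single
    knockouts, lost in the double -> redundant, with a preference suffix when
    one single-knockout modified fraction is lower by at least the margin
    (a deeper drop upon deleting an enzyme means that enzyme contributed more).
    """
    missing = [s for s in STRAINS if s not in states]
    if missing:
        raise TRNAError(f"panel missing strain(s): {missing}")
    wt, db1, db2, dd = (states[s] for s in STRAINS)

    def detected(st: SiteState) -> bool:
        return st.call in ("modified", "reduced")

    if wt.call == "unmodified":
        return "none"
    if dd.call == "modified":
        return "inconsistent"
    if detected(db2) and db1.call == "unmodified":
        return "B1_only"
    if detected(db1) and db2.call == "unmodified":
        return "B2_only"
    if detected(db1) and detected(db2) and dd.call == "unmodified":
        f1, f2 = db1.modified_fraction, db2.modified_fraction
        if f2 <= f1 - preference_margin:
            return "redundant_B2_preferred"
        if f1 <= f2 - preference_margin:
            return "redundant_B1_preferred"
        return "redundant"
    return "inconsistent"


def attribute_panel(peaklists: Mapping[str, PeakList],
                    diagnostics: Sequence[DiagnosticFragment],
                    tolerance_da: float = DEFAULT_TOLERANCE_DA) -> list[SitePanel]:
    """Full grid: match peaks per strain, call states, attribute enzymes."""
    per_strain: dict[str, dict[DiagnosticFragment, tuple[float, float]]] = {}
    floors: dict[str, float] = {}
    for strain in STRAINS:
        if strain not in peaklists:
            raise TRNAError(f"missing peak list for strain {strain}")
        pl = peaklists[strain]
        per_strain[strain] = match_peaks(pl, diagnostics, tolerance_da)
        floors[strain] = UNDETECTED_FLOOR_FRAC * pl.median_intensity()

    panels = []
    for d in diagnostics:
        states = {}
        for strain in STRAINS:
            i_mod, i_unmod = per_strain[strain][d]
            states[strain] = site_state(
                i_mod, i_unmod, site=d.site, trna_id=d.trna_id,
                strain=strain, floor=floors[strain])
        panels.append(SitePanel(d.site, d.trna_id, states,
                                decide_attribution(states)))
    return panels


def read_peak_list(source, strain: str = "") -> PeakList:
    """Two-column TSV (mz, intensity) -> PeakList."""
    df = pd.read_csv(source, sep="\t")
    if not {"mz", "intensity"} <= set(df.columns):
        raise TRNAError("peak list TSV needs columns: mz, intensity")
    return PeakList([Peak(float(r.mz), float(r.intensity))
                     for r in df.itertuples(index=False)], strain=strain)


def panel_report_table(panels: Sequence[SitePanel]) -> pd.DataFrame:
    rows = []
    for p in panels:
        row = {"trna_id": p.trna_id, "site": str(p.site)}
        for strain in STRAINS:
            f = p.fraction(strain)
            row[f"f_{strain}"] = np.nan if f is None else round(f, 4)
        row["attribution"] = p.attribution
        rows.append(row)
    return pd.DataFrame(rows)
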