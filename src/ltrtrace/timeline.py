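"""Dating a transposon invasion from a panel of dated strains.

Strains isolated from the wild are frozen records of the populations they
were sampled from: if an element invaded between two sampling years, strains
collected before the invasion lack it and strains collected after carry it.
The model is therefore a step function in time — absent before a cutoff
year, present from it on — and the invasion is bracketed by the latest
consistent absence and the earliest consistent presence. Real panels carry
occasional contradictions (contaminated stocks, populations the element had
not yet reached); these are handled by choosing the cutoff that minimises
misclassifications under the step model and reporting the misclassified
strains as outliers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["StrainSample", "InvasionWindow", "infer_window", "compare_timelines"]


@dataclass
class StrainSample:
    """A dated, located strain with a presence call for one element."""

    strain: str
    year: int | None
    location: str = ""
    copies: float | None = None
    present: bool = False

    def __post_init__(self) -> None:
        if self.year is not None and not (1800 <= self.year <= 2100):
            raise ValueError(f"implausible sampling year {self.year}")


@dataclass
class InvasionWindow:
    """``(t_lower, t_upper]`` bracket of an invasion.

    ``t_lower`` is the latest year with consistent absence and ``t_upper``
    the earliest year with consistent presence; either side may be undefined
    for an all-absent or all-present panel. ``raw_t_lower``/``raw_t_upper``
    are the same bounds before outlier exclusion.
    """

    t_lower: int | None
    t_upper: int | None
    outliers: list[tuple[str, str]] = field(default_factory=list)
    n_consistent: int = 0
    raw_t_lower: int | None = None
    raw_t_upper: int | None = None
    element: str = ""

    def __post_init__(self) -> None:
        if (
            self.t_lower is not None
            and self.t_upper is not None
            and self.t_lower >= self.t_upper
        ):
            raise ValueError("t_lower must precede t_upper")

    def contains(self, year: int) -> bool:
        """Whether ``year`` lies in the half-open bracket ``(t_lower, t_upper]``."""
        lo_ok = self.t_lower is None or year > self.t_lower
        hi_ok = self.t_upper is None or year <= self.t_upper
        return lo_ok and hi_ok


def infer_window(panel: list[StrainSample], element: str = "") -> InvasionWindow:
    """Fit the step model (absent iff year < cutoff) with the fewest
    misclassified strains; ties go to the earliest cutoff.

    Strains without a sampling year are excluded. Misclassified strains are
    reported as outliers with a reason; the window is computed from the
    consistent strains only, while ``raw_*`` bounds keep every strain.
    """
    dated = [s for s in panel if s.year is not None]
    if not dated:
        raise ValueError("no dated strains in panel")
    years = sorted({s.year for s in dated})
    # candidate cutoffs: before everything, at each observed year, after all
    candidates = [years[0]] + years[1:] + [years[-1] + 1]
    best_c, best_miss = None, None
    for c in candidates:
        miss = sum(
            1 for s in dated if (s.present and s.year < c) or (not s.present and s.year >= c)
        )
        if best_miss is None or miss < best_miss:
            best_c, best_miss = c, miss
    outliers = []
    consistent = []
    for s in dated:
        if s.present and s.year < best_c:
            outliers.append((s.strain, f"present at {s.year}, before inferred cutoff {best_c}"))
        elif not s.present and s.year >= best_c:
            outliers.append((s.strain, f"absent at {s.year}, after inferred cutoff {best_c}"))
        else:
            consistent.append(s)
    absents = [s.year for s in consistent if not s.present]
    presents = [s.year for s in consistent if s.present]
    raw_absents = [s.year for s in dated if not s.present]
    raw_presents = [s.year for s in dated if s.present]
    return InvasionWindow(
        t_lower=max(absents) if absents else None,
        t_upper=min(presents) if presents else None,
        outliers=outliers,
        n_consistent=len(consistent),
        raw_t_lower=max(raw_absents) if raw_absents else None,
        raw_t_upper=min(raw_presents) if raw_presents else None,
        element=element,
    )


def compare_timelines(
    panels: dict[str, list[StrainSample]]
) -> list[InvasionWindow]:
    """One window per element, ordered oldest invasion first (ascending
    ``t_upper``; undefined last; ties by element name)."""
    windows = [infer_window(panel, element=name) for name, panel in panels.items()]
    windows.sort(
        key=lambda w: (w.t_upper is None, w.t_upper, w.element)
    )
    return windows
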