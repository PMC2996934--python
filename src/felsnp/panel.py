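"""Genotyping-panel selection at fixed genomic spacing.

The genome is tiled into windows of the requested spacing (15 kb by default)
and one category-A SNP — the one nearest the window midpoint — is selected
per window.  Windows without an A site can be backfilled from categories B
then C.  Coverage is the fraction of determined windows holding an A
selection, which ties the panel size directly to the window-occupancy curve
at the same window size: the construction behind a "100 k + 20 k = 120 k
chip" style design.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import ReferenceAssembly
from .nqs import VariantSite
from .stats import CategoryPartition, _window_non_n


@dataclass
class Selection:
    site: VariantSite
    category: str  # source category: 'A', 'B' or 'C'
    window_index: int


@dataclass
class PanelDesign:
    spacing: int
    selections: list[Selection]
    windows_total: int
    windows_determined: int
    a_covered_windows: int

    @property
    def covered_fraction(self) -> float:
        if self.windows_determined == 0:
            return 0.0
        return self.a_covered_windows / self.windows_determined

    def counts(self) -> dict[str, int]:
        out = {"A": 0, "B": 0, "C": 0}
        for sel in self.selections:
            out[sel.category] += 1
        return out


def _nearest_mid(cands: list[VariantSite], mid: float) -> VariantSite:
    # tie on distance -> smaller coordinate; cands arrive position-sorted
    return min(cands, key=lambda s: (abs(s.pos - mid), s.pos))


def design_panel(
    partition: CategoryPartition,
    assembly: ReferenceAssembly,
    spacing: int = 15_000,
    backfill: bool = True,
    method: str = "window",
) -> PanelDesign:
    """Select one panel SNP per spacing window from categorized sites.

    ``method='window'`` (default) picks the category-A site nearest each
    window midpoint, backfilling A-less windows from B then C when asked.
    ``method='greedy'`` instead walks A sites left to right keeping any site
    at least ``spacing`` from the previous selection (no backfill, and window
    accounting still reports A-occupied windows).
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if method not in ("window", "greedy"):
        raise ValueError(f"unknown method {method!r}")

    a_sites = partition.sites_in("A")
    b_sites = partition.sites_in("B")
    c_sites = partition.sites_in("C")
    a_keys = {s.key for s in a_sites}
    b_keys = {s.key for s in b_sites}

    selections: list[Selection] = []
    windows_total = windows_determined = a_covered = 0
    global_window = 0
    for chrom in assembly.names:
        L = assembly.length(chrom)
        n_win = (L + spacing - 1) // spacing
        windows_total += n_win
        det = _window_non_n(assembly, chrom, spacing) > 0
        windows_determined += int(det.sum())

        per_window_a: dict[int, list[VariantSite]] = {}
        per_window_b: dict[int, list[VariantSite]] = {}
        per_window_c: dict[int, list[VariantSite]] = {}
        for s in sorted(
            (s for s in c_sites if s.chrom == chrom), key=lambda s: s.pos
        ):
            wdx = s.pos // spacing
            if s.key in a_keys:
                per_window_a.setdefault(wdx, []).append(s)
            elif s.key in b_keys:
                per_window_b.setdefault(wdx, []).append(s)
            else:
                per_window_c.setdefault(wdx, []).append(s)

        a_covered += len(per_window_a)

        if method == "greedy":
            last = None
            for s in sorted(
                (s for s in a_sites if s.chrom == chrom), key=lambda s: s.pos
            ):
                if last is None or s.pos - last >= spacing:
                    selections.append(
                        Selection(site=s, category="A", window_index=global_window + s.pos // spacing)
                    )
                    last = s.pos
        else:
            for wdx in range(n_win):
                mid = wdx * spacing + spacing / 2.0
                if wdx in per_window_a:
                    pick, cat = _nearest_mid(per_window_a[wdx], mid), "A"
                elif backfill and wdx in per_window_b:
                    pick, cat = _nearest_mid(per_window_b[wdx], mid), "B"
                elif backfill and wdx in per_window_c:
                    pick, cat = _nearest_mid(per_window_c[wdx], mid), "C"
                else:
                    continue
                selections.append(
                    Selection(site=pick, category=cat, window_index=global_window + wdx)
                )
        global_window += n_win

    return PanelDesign(
        spacing=spacing,
        selections=selections,
        windows_total=windows_total,
        windows_determined=windows_determined,
        a_covered_windows=a_covered,
    )


def panel_summary(design: PanelDesign) -> dict:
    """Totals, per-category sources, coverage and mean inter-SNP gap."""
    counts = design.counts()
    gaps = []
    by_chrom: dict[str, list[int]] = {}
    for sel in design.selections:
        by_chrom.setdefault(sel.site.chrom, []).append(sel.site.pos)
    for positions in by_chrom.values():
        positions.sort()
        gaps.extend(b - a for a, b in zip(positions, positions[1:]))
    return {
        "total_assays": len(design.selections),
        "a_sourced": counts["A"],
        "backfilled": counts["B"] + counts["C"],
        "covered_fraction": design.covered_fraction,
        "mean_gap": (sum(gaps) / len(gaps)) if gaps else None,
    }


def panel_bed_rows(design: PanelDesign) -> list[tuple]:
    """BED rows (0-based half-open) for the selected sites."""
    rows = []
    for sel in sorted(
        design.selections, key=lambda s: (s.site.chrom, s.site.pos)
    ):
        site = sel.site
        rows.append(
            (
                site.chrom,
                site.pos,
                site.pos + max(1, len(site.ref)),
                f"{site.vtype}:{site.alt or '-'}:{sel.category}",
            )
        )
    return rows
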