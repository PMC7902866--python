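"""Brain parcellation handling.

A :class:`Parcellation` is an ordered table of cerebral regions of interest
(ROIs). The packaged default is the 90-ROI cerebral AAL parcellation
(cerebellum excluded) with each ROI assigned to one of eight lobes per
hemisphere (prefrontal, motorstrip, insula, parietal, temporal, occipital,
limbic, subcortical), i.e. 16 hemisphere-lobe groups. The lobe assignment is
coordinate-based and intentionally user-overridable: pass your own CSV with
columns ``roi_id,name,hemisphere,lobe`` to :func:`load_parcellation`.

The ROI ordering of a parcellation is load-order and defines the feature
ordering of every downstream GMV table and MC feature vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import FormatError

#: The eight lobe names recognised per hemisphere.
LOBES = (
    "prefrontal",
    "motorstrip",
    "insula",
    "parietal",
    "temporal",
    "occipital",
    "limbic",
    "subcortical",
)

_REQUIRED_COLUMNS = ("roi_id", "name", "hemisphere", "lobe")


@dataclass(frozen=True)
class Parcellation:
    """Ordered ROI table with hemisphere and lobe assignments."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in _REQUIRED_COLUMNS if c not in t.columns]
        if missing:
            raise FormatError(f"parcellation table missing columns: {missing}")
        if t["roi_id"].duplicated().any():
            dupes = sorted(t.loc[t["roi_id"].duplicated(), "roi_id"].unique())
            raise FormatError(f"duplicate roi_id values: {dupes}")
        if t["name"].duplicated().any():
            raise FormatError("duplicate ROI names")
        bad_hemi = set(t["hemisphere"]) - {"L", "R"}
        if bad_hemi:
            raise FormatError(f"unknown hemisphere codes: {sorted(bad_hemi)}")
        bad_lobe = set(t["lobe"]) - set(LOBES)
        if bad_lobe:
            raise FormatError(
                f"unknown lobe names: {sorted(bad_lobe)}; allowed: {LOBES}"
            )

    @property
    def n_rois(self) -> int:
        return len(self.table)

    @property
    def roi_ids(self) -> list[int]:
        return [int(i) for i in self.table["roi_id"]]

    @property
    def names(self) -> list[str]:
        return list(self.table["name"])

    @property
    def lobe_groups(self) -> list[tuple[str, str]]:
        """Distinct (hemisphere, lobe) groups, in first-appearance order."""
        seen: dict[tuple[str, str], None] = {}
        for _, row in self.table.iterrows():
            seen.setdefault((row["hemisphere"], row["lobe"]), None)
        return list(seen)

    def hemisphere_lobe(self, roi: int | str) -> str:
        """Return the hemisphere-qualified lobe label, e.g. ``prefrontal_L``."""
        t = self.table
        row = t[t["name"] == roi] if isinstance(roi, str) else t[t["roi_id"] == roi]
        if row.empty:
            raise KeyError(f"ROI {roi!r} not in parcellation")
        r = row.iloc[0]
        return f"{r['lobe']}_{r['hemisphere']}"


def load_parcellation(path: str | Path) -> Parcellation:
    """Load a parcellation from a CSV with columns roi_id,name,hemisphere,lobe."""
    table = pd.read_csv(path)
    return Parcellation(table.reset_index(drop=True))


def default_parcellation() -> Parcellation:
    """The packaged 90-ROI cerebral AAL parcellation with 16 lobe groups."""
    ref = resources.files("mcpain.data").joinpath("aal90_lobes.csv")
    with resources.as_file(ref) as path:
        return load_parcellation(path)


def toy_parcellation(n_rois: int) -> Parcellation:
    """A small synthetic parcellation (``ROI_001`` ...) for simulations.

    Lobes cycle through the eight canonical names, hemispheres alternate, so
    lobe-pair summaries remain exercisable on toy cohorts.
    """
    rows = []
    for i in range(n_rois):
        hemi = "L" if i % 2 == 0 else "R"
        rows.append(
            {
                "roi_id": i + 1,
                "name": f"ROI_{i + 1:03d}_{hemi}",
                "hemisphere": hemi,
                "lobe": LOBES[(i // 2) % len(LOBES)],
            }
        )
    return Parcellation(pd.DataFrame(rows))
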