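"""ROI sets and the shipped mouse atlas hierarchy.

An :class:`ROISet` is an ordered list of ROI labels together with a mapping
from each ROI to one of the atlas's major anatomical divisions.  The package
ships a default hierarchy of nine major divisions containing 31 subregions,
mirroring the whole-brain parcellation used for resting-state connectivity
matrices in small-animal work.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import yaml

__all__ = ["ROISet", "load_default_atlas"]


@dataclass(frozen=True)
class ROISet:
    """Ordered ROI labels with a major-division lookup.

    Parameters
    ----------
    names : list of str
        Unique ROI abbreviations, in matrix order.
    major_region : dict
        Maps each ROI name to exactly one major division label.
    """

    names: tuple[str, ...]
    major_region: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("ROI names must be unique")
        if self.major_region:
            missing = [n for n in self.names if n not in self.major_region]
            if missing:
                raise ValueError(f"ROIs without a major division: {missing}")

    @property
    def n(self) -> int:
        return len(self.names)

    @property
    def divisions(self) -> tuple[str, ...]:
        """Major divisions in first-appearance order."""
        seen: dict[str, None] = {}
        for name in self.names:
            seen.setdefault(self.major_region[name], None)
        return tuple(seen)

    def index(self, name: str) -> int:
        return self.names.index(name)

    @classmethod
    def generic(cls, n: int) -> "ROISet":
        """An unlabeled ROI set (ROI01..ROInn), all in one division."""
        names = tuple(f"ROI{i + 1:02d}" for i in range(n))
        return cls(names, {name: "all" for name in names})


def load_default_atlas() -> ROISet:
    """Load the shipped 9-division / 31-subregion mouse hierarchy."""
    text = resources.files("connscreen.data").joinpath("atlas_mouse31.yaml").read_text()
    doc = yaml.safe_load(text)
    names: list[str] = []
    major: dict[str, str] = {}
    for division, rois in doc["divisions"].items():
        for roi in rois:
            names.append(roi["abbr"])
            major[roi["abbr"]] = division
    return ROISet(tuple(names), major)
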