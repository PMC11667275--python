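"""JHU ICBM-DTI-81 white-matter tract atlas.

The 48 tract labels of the ICBM-DTI-81 atlas, in the conventional label
order, with laterality annotations. Tract-level FA and MD means are indexed
by these names throughout the package; CSV columns use slugged versions
(``fa_<slug>`` / ``md_<slug>``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = ["TractAtlas", "JHU_ICBM_DTI_81", "tract_slug"]

# label, laterality
_TRACTS: list[tuple[str, str]] = [
    ("Middle cerebellar peduncle", "commissural"),
    ("Pontine crossing tract", "commissural"),
    ("Genu of corpus callosum", "commissural"),
    ("Body of corpus callosum", "commissural"),
    ("Splenium of corpus callosum", "commissural"),
    ("Fornix (column and body)", "commissural"),
    ("Corticospinal tract R", "right"),
    ("Corticospinal tract L", "left"),
    ("Medial lemniscus R", "right"),
    ("Medial lemniscus L", "left"),
    ("Inferior cerebellar peduncle R", "right"),
    ("Inferior cerebellar peduncle L", "left"),
    ("Superior cerebellar peduncle R", "right"),
    ("Superior cerebellar peduncle L", "left"),
    ("Cerebral peduncle R", "right"),
    ("Cerebral peduncle L", "left"),
    ("Anterior limb of internal capsule R", "right"),
    ("Anterior limb of internal capsule L", "left"),
    ("Posterior limb of internal capsule R", "right"),
    ("Posterior limb of internal capsule L", "left"),
    ("Retrolenticular part of internal capsule R", "right"),
    ("Retrolenticular part of internal capsule L", "left"),
    ("Anterior corona radiata R", "right"),
    ("Anterior corona radiata L", "left"),
    ("Superior corona radiata R", "right"),
    ("Superior corona radiata L", "left"),
    ("Posterior corona radiata R", "right"),
    ("Posterior corona radiata L", "left"),
    ("Posterior thalamic radiation R", "right"),
    ("Posterior thalamic radiation L", "left"),
    ("Sagittal stratum R", "right"),
    ("Sagittal stratum L", "left"),
    ("External capsule R", "right"),
    ("External capsule L", "left"),
    ("Cingulum (cingulate gyrus) R", "right"),
    ("Cingulum (cingulate gyrus) L", "left"),
    ("Cingulum (hippocampus) R", "right"),
    ("Cingulum (hippocampus) L", "left"),
    ("Fornix (cres) / Stria terminalis R", "right"),
    ("Fornix (cres) / Stria terminalis L", "left"),
    ("Superior longitudinal fasciculus R", "right"),
    ("Superior longitudinal fasciculus L", "left"),
    ("Superior fronto-occipital fasciculus R", "right"),
    ("Superior fronto-occipital fasciculus L", "left"),
    ("Uncinate fasciculus R", "right"),
    ("Uncinate fasciculus L", "left"),
    ("Tapetum R", "right"),
    ("Tapetum L", "left"),
]


def tract_slug(name: str) -> str:
    """Lower-case, alphanumeric-and-underscore column slug for a tract label."""
    return re.sub(r"_+", "_", re.sub(r"[^a-z0-9]+", "_", name.lower())).strip("_")


@dataclass(frozen=True)
class TractAtlas:
    """Ordered tract labels with laterality; defaults to the 48 JHU tracts."""

    names: tuple[str, ...] = tuple(t[0] for t in _TRACTS)
    laterality: tuple[str, ...] = tuple(t[1] for t in _TRACTS)
    _index: dict = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self):
        if len(self.names) != len(self.laterality):
            raise ValueError("names and laterality must have equal length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("tract labels must be unique")
        object.__setattr__(self, "_index", {n: i for i, n in enumerate(self.names)})

    def __len__(self) -> int:
        return len(self.names)

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def index(self, name: str) -> int:
        return self._index[name]

    @property
    def slugs(self) -> tuple[str, ...]:
        return tuple(tract_slug(n) for n in self.names)

    def fa_columns(self) -> list[str]:
        return [f"fa_{s}" for s in self.slugs]

    def md_columns(self) -> list[str]:
        return [f"md_{s}" for s in self.slugs]

    def metric_columns(self) -> list[str]:
        """All 96 tract-metric column names, FA block then MD block."""
        return self.fa_columns() + self.md_columns()

    def column(self, name: str, metric: str) -> str:
        """Column name for a (tract label, 'FA'|'MD') pair."""
        m = metric.lower()
        if m not in ("fa", "md"):
            raise ValueError(f"metric must be FA or MD, got {metric!r}")
        if name not in self:
            raise KeyError(f"unknown tract label: {name!r}")
        return f"{m}_{tract_slug(name)}"


JHU_ICBM_DTI_81 = TractAtlas()
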