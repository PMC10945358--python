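"""Factorial sampling designs for paired peatland surveys.

The emulated survey is a fully crossed design: peatland sites, each
containing a natural and an adjacent cultivated stand, with replicate plots
per stand and two sampling depths per plot. The default —
3 sites x 2 land-use types x 4 plots x 2 depths — yields 48 composite
samples, each a pooled core from five subplots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["DesignSpec", "generate_design"]

DEPTH_LEVELS = ("0-15 cm", "15-30 cm")
LAND_USE_LEVELS = ("natural", "cultivated")


@dataclass(frozen=True)
class DesignSpec:
    """A crossed site x land-use x plot x depth sampling design."""

    n_sites: int = 3
    site_labels: tuple[str, ...] = ("JC", "SP", "YSJ")
    n_types: int = 2
    type_labels: tuple[str, ...] = LAND_USE_LEVELS
    n_plots_per_type: int = 4
    n_depths: int = 2
    depth_labels: tuple[str, ...] = DEPTH_LEVELS

    def __post_init__(self) -> None:
        for name in ("n_sites", "n_types", "n_plots_per_type", "n_depths"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if len(self.site_labels) < self.n_sites:
            object.__setattr__(
                self,
                "site_labels",
                tuple(self.site_labels) + tuple(
                    f"S{i + 1}" for i in range(len(self.site_labels), self.n_sites)
                ),
            )
        if len(self.type_labels) < self.n_types:
            raise ValueError("need a label per land-use type")
        if len(self.depth_labels) < self.n_depths:
            raise ValueError("need a label per depth")

    @property
    def n_samples(self) -> int:
        return self.n_sites * self.n_types * self.n_plots_per_type * self.n_depths


def generate_design(spec: DesignSpec = DesignSpec()) -> pd.DataFrame:
    """Enumerate the composite samples of a design.

    Returns a metadata table indexed by sample ID (``site-type-plot-depth``)
    with columns ``site``, ``land_use``, ``plot``, ``depth``. The row count
    equals the design product.
    """
    records = []
    for site in spec.site_labels[: spec.n_sites]:
        for land_use in spec.type_labels[: spec.n_types]:
            for plot in range(1, spec.n_plots_per_type + 1):
                for d, depth in enumerate(spec.depth_labels[: spec.n_depths], start=1):
                    sample_id = f"{site}-{land_use[:3].upper()}-P{plot}-D{d}"
                    records.append(
                        {
                            "sample_id": sample_id,
                            "site": site,
                            "land_use": land_use,
                            "plot": f"P{plot}",
                            "depth": depth,
                        }
                    )
    meta = pd.DataFrame.from_records(records).set_index("sample_id")
    assert len(meta) == spec.n_samples
    return meta
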