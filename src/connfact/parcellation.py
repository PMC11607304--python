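"""Region-to-network parcellation tables.

A parcellation fixes the region order shared by every subject's
connectivity matrix and assigns each region to exactly one large-scale
functional network.  The default configuration uses 128 regions grouped
into 9 networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Canonical 9-network labels (visual, somatomotor, dorsal attention,
#: salience/ventral attention, limbic, control, default mode, temporal
#: parietal, subcortical).
DEFAULT_NETWORKS: tuple[str, ...] = (
    "VIS", "SMT", "DAT", "SVA", "LIB", "CON", "DMN", "TMP", "SBC",
)


@dataclass(frozen=True)
class Parcellation:
    """Ordered region labels plus a region → network map.

    Parameters
    ----------
    region_ids : sequence of str
        Region labels in the fixed order used by all connectivity
        matrices.
    network_of : mapping str -> str
        Network label for every region id.
    """

    region_ids: tuple[str, ...]
    network_of: Mapping[str, str]
    networks: tuple[str, ...] = field(default=DEFAULT_NETWORKS)

    def __post_init__(self) -> None:
        if len(set(self.region_ids)) != len(self.region_ids):
            raise ValueError("region_ids must be unique")
        missing = [r for r in self.region_ids if r not in self.network_of]
        if missing:
            raise ValueError(f"regions without a network assignment: {missing[:5]}")
        bad = sorted({self.network_of[r] for r in self.region_ids} - set(self.networks))
        if bad:
            raise ValueError(f"unknown network labels: {bad}")

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    @property
    def n_edges(self) -> int:
        r = self.n_regions
        return r * (r - 1) // 2

    def network_indices(self) -> np.ndarray:
        """Integer network index (into ``self.networks``) per region."""
        lookup = {name: i for i, name in enumerate(self.networks)}
        return np.array([lookup[self.network_of[r]] for r in self.region_ids])

    @classmethod
    def default(cls, n_regions: int = 128,
                networks: Sequence[str] = DEFAULT_NETWORKS) -> "Parcellation":
        """Evenly partition ``n_regions`` regions over ``networks`` in
        contiguous blocks (remainder spread over the first networks)."""
        networks = tuple(networks)
        base, extra = divmod(n_regions, len(networks))
        region_ids, network_of = [], {}
        idx = 0
        for k, net in enumerate(networks):
            size = base + (1 if k < extra else 0)
            for _ in range(size):
                rid = f"R{idx + 1:03d}"
                region_ids.append(rid)
                network_of[rid] = net
                idx += 1
        return cls(tuple(region_ids), network_of, networks)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "Parcellation":
        """Read a TSV with columns region_id, region_name, network."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"region_id", "network"}
        if not required.issubset(df.columns):
            raise ValueError(f"parcellation TSV needs columns {sorted(required)}")
        networks = tuple(dict.fromkeys(df["network"]))
        return cls(tuple(df["region_id"]),
                   dict(zip(df["region_id"], df["network"])),
                   networks)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({
            "region_id": self.region_ids,
            "region_name": self.region_ids,
            "network": [self.network_of[r] for r in self.region_ids],
        }).to_csv(path, sep="\t", index=False)
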