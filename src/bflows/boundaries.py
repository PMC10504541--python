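"""Downscaling global planetary boundaries to national boundaries.

Each country's share of a global boundary is allocated by a proxy ratio:
the national proxy value divided by its global total,

    NB_e^r = PB_e * proxy_{m(e)}^r / sum_r' proxy_{m(e)}^r'

where m(e) maps the indicator to its proxy — renewable water availability
for water, nitrogen and phosphorus; farmland area for land.  The national
boundaries therefore partition the global boundary exactly, and are
invariant to rescaling all proxies by a common factor.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import (
    DEFAULT_PROXY_MAPPING,
    INDICATORS,
    NationalBoundarySet,
    PlanetaryBoundarySet,
    ProxyTable,
    ValidationError,
)


def downscale_boundaries(
    pb: PlanetaryBoundarySet,
    proxies: ProxyTable,
    proxy_mapping: dict[str, str] | None = None,
    overrides: dict[str, dict[str, float]] | None = None,
) -> NationalBoundarySet:
    """Allocate each global boundary across regions in proportion to its proxy.

    Parameters
    ----------
    pb
        Global boundaries per indicator (internal units).
    proxies
        Per-region proxy table; the mapped proxy must be nonnegative with a
        positive global total for every indicator.
    proxy_mapping
        Indicator -> proxy column.  Defaults to water availability for
        water/nitrogen/phosphorus and farmland area for land.
    overrides
        Optional ``{indicator: {region: boundary}}`` replacing the downscaled
        value for specific regions (e.g. externally assessed regional
        boundaries).  Overridden values are excluded from the partition
        identity.

    Returns
    -------
    NationalBoundarySet
        Indicator x region boundaries; regions with a zero proxy receive a
        zero boundary.
    """
    pb.validate()
    mapping = dict(DEFAULT_PROXY_MAPPING)
    if proxy_mapping:
        mapping.update(proxy_mapping)
    regions = proxies.regions
    pb_series = pb.as_series()
    rows = {}
    provenance = {}
    for ind in INDICATORS:
        proxy_name = mapping[ind]
        if proxy_name not in proxies.table.columns:
            raise ValidationError(
                f"boundaries: proxy {proxy_name!r} mapped to {ind!r} not in proxy table"
            )
        p = proxies.table[proxy_name].to_numpy(dtype=float)
        if (p < 0).any():
            r = regions[int(np.argwhere(p < 0)[0][0])]
            raise ValidationError(
                f"boundaries: negative proxy {proxy_name!r} for region {r!r}"
            )
        total = p.sum()
        if total <= 0:
            raise ValidationError(
                f"boundaries: proxy {proxy_name!r} for indicator {ind!r} "
                "has zero global total; cannot downscale"
            )
        rows[ind] = pb_series[ind] * p / total
        provenance[ind] = proxy_name
    nb = pd.DataFrame(rows, index=regions).T.reindex(list(INDICATORS))
    nb.index.name = "indicator"
    nb.columns.name = "region"
    if overrides:
        for ind, per_region in overrides.items():
            for region, value in per_region.items():
                if region not in nb.columns:
                    raise ValidationError(
                        f"boundaries: override for unknown region {region!r}"
                    )
                if value < 0:
                    raise ValidationError(
                        f"boundaries: negative override for {ind!r}/{region!r}"
                    )
                nb.loc[ind, region] = float(value)
                provenance[ind] = f"{provenance[ind]} (override: {region})"
    return NationalBoundarySet(NB=nb, provenance=provenance)
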