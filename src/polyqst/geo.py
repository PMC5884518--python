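"""Great-circle geographic distances from site coordinates."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_io import SiteTable

EARTH_RADIUS_KM = 6371.0


def haversine_km(lon1, lat1, lon2, lat2) -> float:
    """Great-circle distance in km between two lon/lat points (degrees)."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlon, dlat = lon2 - lon1, lat2 - lat1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h)))


def great_circle_matrix(
    sites: SiteTable, individuals: list[str], populations: list[str]
) -> pd.DataFrame:
    """Individual x individual geographic distance via each one's site."""
    site = sites.data.set_index("population_id")
    if not {"lon", "lat"} <= set(site.columns):
        raise ValueError("site table lacks lon/lat columns")
    pops = sorted(set(populations))
    pairwise = {}
    for p1 in pops:
        for p2 in pops:
            pairwise[(p1, p2)] = haversine_km(
                site.loc[p1, "lon"], site.loc[p1, "lat"],
                site.loc[p2, "lon"], site.loc[p2, "lat"],
            )
    n = len(individuals)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = pairwise[(populations[i], populations[j])]
    return pd.DataFrame(D, index=individuals, columns=individuals)
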