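"""Embedded reference datasets: two cohorts from a Milan labour ward.

Aggregate counts from a prospective before/after study of a labour-ward
management protocol ("BCM" = before, "ACM" = after): per-path counts of women
over the three-intervention protocol (augmentation, ventouse, caesarean), and
per-Robson-class women/caesarean counts.  All values are printed aggregate
integers; no individual-level data are included.
"""

from __future__ import annotations

from .protocol import DEFAULT_PROTOCOL, PathCountTable
from .robson import RobsonClassCounts

__all__ = ["load_fixture", "FIXTURES"]

_TABLE7_BCM = {
    (0, 0, 0): 387,
    (1, 0, 0): 160,
    (0, 1, 0): 9,
    (0, 0, 1): 25,
    (1, 1, 0): 16,
    (1, 0, 1): 38,
    (0, 1, 1): 1,
    (1, 1, 1): 1,
}

_TABLE7_ACM = {
    (0, 0, 0): 969,
    (1, 0, 0): 245,
    (0, 1, 0): 36,
    (0, 0, 1): 51,
    (1, 1, 0): 27,
    (1, 0, 1): 44,
    (0, 1, 1): 2,
    (1, 1, 1): 1,
}

_TABLE2_BCM = [
    ("I", 245, 20),
    ("IIa", 107, 36),
    ("IIb", 43, 43),
    ("III", 232, 3),
    ("IVa", 53, 6),
    ("IVb", 11, 11),
    ("V", 99, 79),
    ("VI", 34, 34),
    ("VII", 10, 7),
    ("VIII", 18, 15),
    ("IX", 2, 2),
    ("X", 58, 29),
]

_TABLE2_ACM = [
    ("I", 580, 35),
    ("IIa", 196, 49),
    ("IIb", 41, 41),
    ("III", 527, 10),
    ("IVa", 72, 4),
    ("IVb", 13, 13),
    ("V", 196, 165),
    ("VI", 44, 44),
    ("VII", 33, 29),
    ("VIII", 65, 54),
    ("IX", 11, 11),
    ("X", 127, 54),
]

FIXTURES = ("table7_bcm", "table7_acm", "table2_bcm", "table2_acm")


def load_fixture(name: str):
    """Return an embedded reference dataset by name.

    ``table7_bcm``/``table7_acm`` give :class:`~labourpath.protocol.PathCountTable`
    objects on the default (A, V, C) protocol (N = 637 and 1375);
    ``table2_bcm``/``table2_acm`` give lists of
    :class:`~labourpath.robson.RobsonClassCounts` (totals 912/285 and
    1905/509 women/caesareans).
    """
    if name == "table7_bcm":
        return PathCountTable(DEFAULT_PROTOCOL, dict(_TABLE7_BCM), stratum="BCM")
    if name == "table7_acm":
        return PathCountTable(DEFAULT_PROTOCOL, dict(_TABLE7_ACM), stratum="ACM")
    if name == "table2_bcm":
        return [RobsonClassCounts(*row) for row in _TABLE2_BCM]
    if name == "table2_acm":
        return [RobsonClassCounts(*row) for row in _TABLE2_ACM]
    raise KeyError(f"unknown fixture {name!r}; available: {FIXTURES}")
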