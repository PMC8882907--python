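"""Node (region) tables for cortical parcellation schemes.

The default scheme is the 68-region Desikan-Killiany gyral parcellation,
34 regions per hemisphere, the standard cortical node definition for
structural connectomes built from anatomical parcellation.  The exact
region list of any given study may differ slightly in naming; the gyral
set below is the standard FreeSurfer ``aparc`` table and is documented
as an assumption of this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["NodeTable", "desikan_killiany"]

# (label, abbreviation) for one hemisphere of the Desikan-Killiany gyral
# parcellation.  Abbreviations follow common connectomics usage
# (cMFG, IsC, PCUN, Tpole, BSTS, ...).
_DK_REGIONS: list[tuple[str, str]] = [
    ("bankssts", "BSTS"),
    ("caudalanteriorcingulate", "cACC"),
    ("caudalmiddlefrontal", "cMFG"),
    ("cuneus", "CUN"),
    ("entorhinal", "ENT"),
    ("fusiform", "FUS"),
    ("inferiorparietal", "IPL"),
    ("inferiortemporal", "ITG"),
    ("isthmuscingulate", "IsC"),
    ("lateraloccipital", "LOC"),
    ("lateralorbitofrontal", "lOFC"),
    ("lingual", "LING"),
    ("medialorbitofrontal", "mOFC"),
    ("middletemporal", "MTG"),
    ("parahippocampal", "PHG"),
    ("paracentral", "PaCL"),
    ("parsopercularis", "pOPER"),
    ("parsorbitalis", "pORB"),
    ("parstriangularis", "pTRI"),
    ("pericalcarine", "PCAL"),
    ("postcentral", "PoCG"),
    ("posteriorcingulate", "PCC"),
    ("precentral", "PrCG"),
    ("precuneus", "PCUN"),
    ("rostralanteriorcingulate", "rACC"),
    ("rostralmiddlefrontal", "rMFG"),
    ("superiorfrontal", "SFG"),
    ("superiorparietal", "SPC"),
    ("superiortemporal", "STG"),
    ("supramarginal", "SMG"),
    ("frontalpole", "FP"),
    ("temporalpole", "Tpole"),
    ("transversetemporal", "TrT"),
    ("insula", "INS"),
]


@dataclass(frozen=True)
class NodeTable:
    """Ordered table of network nodes (cortical regions).

    Parameters
    ----------
    labels : tuple of str
        Full region names, unique, one per node.
    abbreviations : tuple of str
        Short codes, unique, hemisphere-prefixed (e.g. ``L.cMFG``).
    hemispheres : tuple of str
        ``"L"`` or ``"R"`` per node.

    Node identity is by label; the row order defines the 0-based matrix
    index used everywhere else in the package.
    """

    labels: tuple[str, ...]
    abbreviations: tuple[str, ...]
    hemispheres: tuple[str, ...]
    _abbr_index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        n = len(self.labels)
        if not (len(self.abbreviations) == len(self.hemispheres) == n):
            raise ValueError("labels, abbreviations and hemispheres must have equal length")
        if len(set(self.labels)) != n:
            raise ValueError("node labels must be unique")
        if len(set(self.abbreviations)) != n:
            raise ValueError("node abbreviations must be unique")
        bad = set(self.hemispheres) - {"L", "R"}
        if bad:
            raise ValueError(f"hemisphere codes must be 'L' or 'R', got {sorted(bad)}")
        object.__setattr__(
            self, "_abbr_index", {a: i for i, a in enumerate(self.abbreviations)}
        )

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    def index_of(self, abbreviation: str) -> int:
        """Matrix index of a node given its abbreviation."""
        try:
            return self._abbr_index[abbreviation]
        except KeyError:
            raise KeyError(f"unknown node abbreviation: {abbreviation!r}") from None

    def hemisphere_mask(self, hemisphere: str) -> np.ndarray:
        """Boolean mask of nodes in one hemisphere."""
        return np.asarray([h == hemisphere for h in self.hemispheres])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": np.arange(len(self)),
                "label": self.labels,
                "abbreviation": self.abbreviations,
                "hemisphere": self.hemispheres,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "NodeTable":
        df = df.sort_values("index")
        if not np.array_equal(df["index"].to_numpy(), np.arange(len(df))):
            raise ValueError("node indices must be contiguous 0..N-1")
        return cls(
            labels=tuple(df["label"]),
            abbreviations=tuple(df["abbreviation"]),
            hemispheres=tuple(df["hemisphere"]),
        )

    @classmethod
    def from_tsv(cls, path) -> "NodeTable":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


def desikan_killiany() -> NodeTable:
    """Default 68-node Desikan-Killiany cortical scheme (34 per hemisphere).

    Left-hemisphere nodes occupy indices 0-33, right-hemisphere nodes
    34-67.  Abbreviations are prefixed ``L.`` / ``R.``.
    """
    labels, abbrs, hemis = [], [], []
    for hemi, prefix in (("L", "lh"), ("R", "rh")):
        for label, abbr in _DK_REGIONS:
            labels.append(f"{prefix}-{label}")
            abbrs.append(f"{hemi}.{abbr}")
            hemis.append(hemi)
    return NodeTable(tuple(labels), tuple(abbrs), tuple(hemis))
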