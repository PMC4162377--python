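"""Containers for multi-group binary response data.

Responses are held as one rectangular block per group: a float array of
shape (n_g, P) with entries 0.0, 1.0 or NaN (missing).  Group labels are
opaque — they are never parsed or ordered numerically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Hashable, List, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = ["ResponseData", "ResponseDataError", "DEFAULT_MISSING_CODES"]

#: Cell values treated as missing when building from tabular input.
DEFAULT_MISSING_CODES: Tuple[str, ...] = ("", "NA", "-9")


class ResponseDataError(ValueError):
    """Raised when response data violate the container's invariants."""


def _validate_block(label, block: np.ndarray, items: Sequence[str]) -> np.ndarray:
    block = np.asarray(block, dtype=float)
    if block.ndim != 2:
        raise ResponseDataError(f"group {label!r}: block must be 2-D")
    if block.shape[0] < 1:
        raise ResponseDataError(f"group {label!r} has no respondents")
    if block.shape[1] != len(items):
        raise ResponseDataError(
            f"group {label!r}: {block.shape[1]} columns but {len(items)} items"
        )
    bad = ~(np.isnan(block) | (block == 0.0) | (block == 1.0))
    if np.any(bad):
        r, c = np.argwhere(bad)[0]
        raise ResponseDataError(
            f"group {label!r}: non-binary value {block[r, c]!r} at "
            f"row {r}, item {items[c]!r}"
        )
    all_missing = np.all(np.isnan(block), axis=0)
    if np.any(all_missing):
        missing_items = [items[j] for j in np.flatnonzero(all_missing)]
        raise ResponseDataError(
            f"group {label!r} has missing data for everyone on item(s) "
            f"{missing_items}; such groups must be excluded before analysis"
        )
    return block


@dataclass
class ResponseData:
    """Binary item responses partitioned by group.

    Invariants: at least 2 groups and 2 items; every group has at least one
    respondent; within a group no item is missing for every respondent.
    """

    items: List[str]
    blocks: Dict[Hashable, np.ndarray] = field(repr=False)

    def __post_init__(self):
        self.items = [str(i) for i in self.items]
        if len(self.items) < 2:
            raise ResponseDataError("at least 2 items are required")
        if len(set(self.items)) != len(self.items):
            raise ResponseDataError("item labels must be unique")
        if len(self.blocks) < 2:
            raise ResponseDataError("at least 2 groups are required")
        self.blocks = {
            label: _validate_block(label, block, self.items)
            for label, block in self.blocks.items()
        }

    @property
    def groups(self) -> List[Hashable]:
        return list(self.blocks.keys())

    @property
    def n_groups(self) -> int:
        return len(self.blocks)

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def group_sizes(self) -> Dict[Hashable, int]:
        return {label: block.shape[0] for label, block in self.blocks.items()}

    @property
    def n_total(self) -> int:
        return sum(b.shape[0] for b in self.blocks.values())

    def block(self, label) -> np.ndarray:
        return self.blocks[label]

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        group_column: str = "group",
        missing_codes: Sequence = DEFAULT_MISSING_CODES,
    ) -> "ResponseData":
        """Build from a wide table: one row per respondent, one column per item.

        Cells must be 0, 1 or one of ``missing_codes``; anything else raises
        with the offending row/column named.
        """
        if group_column not in df.columns:
            raise ResponseDataError(f"missing group column {group_column!r}")
        items = [c for c in df.columns if c != group_column]
        missing = {str(m) for m in missing_codes}

        def parse_cell(value, row, col):
            if value is None or (isinstance(value, float) and np.isnan(value)):
                return np.nan
            text = str(value).strip()
            if text in missing or text == "nan":
                return np.nan
            try:
                num = float(text)
            except ValueError:
                num = None
            if num in (0.0, 1.0):
                return num
            if num is not None and num in {float(m) for m in missing if _is_number(m)}:
                return np.nan
            raise ResponseDataError(
                f"invalid response {value!r} at row {row!r}, column {col!r}: "
                "expected 0, 1 or a missing code"
            )

        blocks: Dict[Hashable, np.ndarray] = {}
        for label, sub in df.groupby(group_column, sort=False):
            arr = np.empty((len(sub), len(items)), dtype=float)
            for j, col in enumerate(items):
                for i, (row_label, value) in enumerate(sub[col].items()):
                    arr[i, j] = parse_cell(value, row_label, col)
            blocks[label] = arr
        return cls(items=items, blocks=blocks)

    def to_dataframe(self, group_column: str = "group") -> pd.DataFrame:
        """Inverse of :meth:`from_dataframe` (missing cells become NaN)."""
        frames = []
        for label, block in self.blocks.items():
            sub = pd.DataFrame(block, columns=self.items)
            sub.insert(0, group_column, label)
            frames.append(sub)
        return pd.concat(frames, ignore_index=True)


def _is_number(text) -> bool:
    try:
        float(str(text))
        return True
    except ValueError:
        return False
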