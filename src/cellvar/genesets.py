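"""Named gene sets (GO terms, marker panels) with GMT read/write.

GMT is the tab-separated gene-set format: one set per line, fields are
set name, description, then member gene IDs.
"""

from __future__ import annotations

from collections.abc import Iterable, Iterator, Mapping
from pathlib import Path


class GeneSetCollection(Mapping[str, list[str]]):
    """An ordered mapping of set name -> member gene IDs.

    Membership lists preserve input order and are de-duplicated.
    Descriptions are kept alongside for GMT round-trips.
    """

    def __init__(
        self,
        sets: Mapping[str, Iterable[str]] | None = None,
        descriptions: Mapping[str, str] | None = None,
    ) -> None:
        self._sets: dict[str, list[str]] = {}
        self._desc: dict[str, str] = {}
        if sets:
            for name, members in sets.items():
                self.add(name, members, (descriptions or {}).get(name, ""))

    def add(self, name: str, members: Iterable[str], description: str = "") -> None:
        seen: dict[str, None] = dict.fromkeys(str(m) for m in members)
        self._sets[str(name)] = list(seen)
        self._desc[str(name)] = description

    def description(self, name: str) -> str:
        return self._desc[name]

    def subset_present(self, name: str, universe: Iterable[str]) -> list[str]:
        """Members of `name` that exist in `universe`, in set order."""
        present = set(universe)
        return [g for g in self._sets[name] if g in present]

    def __getitem__(self, name: str) -> list[str]:
        return self._sets[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._sets)

    def __len__(self) -> int:
        return len(self._sets)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"GeneSetCollection({len(self)} sets)"

    @classmethod
    def from_gmt(cls, path: str | Path) -> "GeneSetCollection":
        coll = cls()
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValueError(
                        f"{path}:{lineno}: GMT line needs >=3 tab-separated fields "
                        "(name, description, members)"
                    )
                coll.add(fields[0], fields[2:], fields[1])
        return coll

    def to_gmt(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, members in self._sets.items():
                fh.write("\t".join([name, self._desc.get(name, "")] + members) + "\n")
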