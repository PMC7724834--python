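"""Set-based evaluation of per-user location inferences.

Because a user's true location is itself a set (hometown, workplace,
places migrated between), ordinary precision/recall over single labels does
not apply.  Four per-user set relations against the gold set G for an
inferred set I are counted over all evaluated users:

* **S** (absolute accuracy / success rate): I = G
* **C** (coverage ratio): G ⊆ I
* **T** (targeting ratio): I ⊆ G and I ≠ ∅
* **P** (partial accuracy): I ∩ G ≠ ∅

Each ratio divides its user count by N_all, the number of evaluated users.
An empty inferred set deliberately earns no credit under T: abstention is
not correctness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Union

import pandas as pd

from .errors import EvaluationError
from .gazetteer import AdminUnit, Gazetteer

METRIC_NAMES = ("S", "C", "T", "P")


@dataclass
class MetricsReport:
    n_all: int
    n_s: int
    n_c: int
    n_t: int
    n_p: int
    per_user_flags: dict = field(default_factory=dict)

    @property
    def S(self) -> float:
        return self.n_s / self.n_all

    @property
    def C(self) -> float:
        return self.n_c / self.n_all

    @property
    def T(self) -> float:
        return self.n_t / self.n_all

    @property
    def P(self) -> float:
        return self.n_p / self.n_all

    def ratios(self) -> dict[str, float]:
        return {"S": self.S, "C": self.C, "T": self.T, "P": self.P}

    def to_dict(self) -> dict:
        return {
            "N_all": self.n_all,
            "N_s": self.n_s,
            "N_c": self.n_c,
            "N_T": self.n_t,
            "N_P": self.n_p,
            **self.ratios(),
            "per_user_flags": {
                uid: {"s": f[0], "c": f[1], "t": f[2], "p": f[3]}
                for uid, f in self.per_user_flags.items()
            },
        }

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), ensure_ascii=False, sort_keys=True, indent=1),
            encoding="utf-8",
        )


def _as_pairs(units) -> frozenset:
    """Compare locations as (canonical_name, level) pairs."""
    out = set()
    for u in units:
        if isinstance(u, AdminUnit):
            out.add((u.canonical_name, u.level))
        else:
            out.add(tuple(u))
    return frozenset(out)


def compute_metrics(
    pred: Mapping[str, frozenset], gold: Mapping[str, frozenset]
) -> MetricsReport:
    """Score per-user predicted sets against gold sets.

    Every gold user must be present in ``pred`` (an empty set is a valid
    prediction); extra predicted users are ignored.  N_all = |gold|.
    """
    if not gold:
        raise EvaluationError("gold labels are empty")
    missing = sorted(set(gold) - set(pred))
    if missing:
        raise EvaluationError(
            f"{len(missing)} gold user(s) missing from predictions: "
            + ", ".join(missing[:10])
        )
    n_s = n_c = n_t = n_p = 0
    flags = {}
    for uid, gold_units in gold.items():
        G = _as_pairs(gold_units)
        if not G:
            raise EvaluationError(f"gold set for user {uid!r} is empty")
        I = _as_pairs(pred[uid])
        c = G <= I
        t = bool(I) and I <= G
        s = c and t
        p = bool(I & G)
        n_s += s
        n_c += c
        n_t += t
        n_p += p
        flags[uid] = (s, c, t, p)
    return MetricsReport(
        n_all=len(gold), n_s=n_s, n_c=n_c, n_t=n_t, n_p=n_p, per_user_flags=flags
    )


def read_gold(source: Union[str, Path], gaz: Gazetteer) -> dict[str, frozenset]:
    """Read gold labels (JSONL: user_id, locations=[{name, level}]).

    Names are canonicalized against the gazetteer, so suffixed forms
    (长沙市, 四川省) are accepted.
    """
    out: dict[str, frozenset] = {}
    with open(Path(source), encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            units = set()
            for d in rec["locations"]:
                matches = {
                    u for u in gaz.canonicalize(d["name"]) if u.level == d["level"]
                }
                if not matches:
                    raise EvaluationError(
                        f"line {lineno}: gold location {d['name']!r}/{d['level']} "
                        "not in gazetteer"
                    )
                units |= matches
            out[rec["user_id"]] = frozenset(units)
    return out


def write_gold(gold: Mapping[str, frozenset], target: Union[str, Path]) -> None:
    with open(Path(target), "w", encoding="utf-8") as fh:
        for uid in sorted(gold):
            locs = sorted(gold[uid], key=lambda u: (u.level, u.canonical_name))
            fh.write(
                json.dumps(
                    {
                        "user_id": uid,
                        "locations": [
                            {"name": u.canonical_name, "level": u.level} for u in locs
                        ],
                    },
                    ensure_ascii=False,
                    sort_keys=True,
                )
                + "\n"
            )


def benchmark_report(runs: Mapping[str, MetricsReport]) -> pd.DataFrame:
    """Rows S, C, T, P; one column per run."""
    if not runs:
        raise EvaluationError("benchmark_report requires at least one run")
    return pd.DataFrame(
        {name: [rep.S, rep.C, rep.T, rep.P] for name, rep in runs.items()},
        index=list(METRIC_NAMES),
    )


def format_benchmark(runs: Mapping[str, MetricsReport], digits: int = 3) -> str:
    """Markdown table with the per-row maximum flagged in bold (ties all)."""
    df = benchmark_report(runs)
    cols = list(df.columns)
    lines = ["| | " + " | ".join(cols) + " |", "|---" * (len(cols) + 1) + "|"]
    for metric in df.index:
        row = df.loc[metric]
        best = row.max()
        cells = [
            f"**{v:.{digits}f}**" if v == best else f"{v:.{digits}f}" for v in row
        ]
        lines.append(f"| {metric} | " + " | ".join(cells) + " |")
    return "\n".join(lines)
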