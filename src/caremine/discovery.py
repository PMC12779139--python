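"""Directly-follows process-map discovery, importance zoom, and DOT rendering.

The mined map is a directly-follows graph: an arrow from A to B exists iff at
least one case performs B immediately after A with no intermediate activity.
Edges carry both frequency annotations (occurrences and case coverage) and
performance annotations (the multiset of day gaps between the two
activities), so the same map backs a frequency view, a performance view, or
a mixed view with secondary labels.

The importance zoom keeps the top fraction of activities (by case coverage)
and of paths (by occurrences), then repairs connectivity so that no depicted
activity is disconnected from the start or the end of the process.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import networkx as nx

from .eventlog import EventLog

STATISTICS = ("median", "mean", "total")


def _median(values: list[int]) -> float:
    s = sorted(values)
    n = len(s)
    mid = n // 2
    return float(s[mid]) if n % 2 else (s[mid - 1] + s[mid]) / 2.0


@dataclass
class ActivityStats:
    """Absolute event count and number of cases containing the activity."""

    occurrences: int = 0
    case_coverage: int = 0


@dataclass
class EdgeStats:
    """Stats of one directly-follows transition: total adjacent-pair count
    (self-loops included), number of cases containing the transition at least
    once, and the multiset of day gaps between source and target."""

    occurrences: int = 0
    case_coverage: int = 0
    gaps: list[int] = field(default_factory=list)

    @property
    def median_days(self) -> float:
        return _median(self.gaps)

    @property
    def mean_days(self) -> float:
        return sum(self.gaps) / len(self.gaps)

    @property
    def total_days(self) -> float:
        return float(sum(self.gaps))

    def statistic(self, name: str) -> float:
        if name == "median":
            return self.median_days
        if name == "mean":
            return self.mean_days
        if name == "total":
            return self.total_days
        raise ValueError(f"unknown statistic {name!r}")


@dataclass
class ProcessMap:
    """Activities, directly-follows edges, and dashed start/end markers."""

    n_cases: int
    activities: dict[str, ActivityStats] = field(default_factory=dict)
    edges: dict[tuple[str, str], EdgeStats] = field(default_factory=dict)
    start_counts: dict[str, int] = field(default_factory=dict)
    end_counts: dict[str, int] = field(default_factory=dict)

    def activity_coverage_pct(self, activity: str) -> float:
        return 100.0 * self.activities[activity].case_coverage / self.n_cases

    def edge_coverage_pct(self, edge: tuple[str, str]) -> float:
        return 100.0 * self.edges[edge].case_coverage / self.n_cases

    def relabel(self, mapping: dict[str, str]) -> "ProcessMap":
        m = lambda a: mapping.get(a, a)
        return ProcessMap(
            n_cases=self.n_cases,
            activities={m(a): s for a, s in self.activities.items()},
            edges={(m(s), m(t)): st for (s, t), st in self.edges.items()},
            start_counts={m(a): c for a, c in self.start_counts.items()},
            end_counts={m(a): c for a, c in self.end_counts.items()},
        )


@dataclass
class ViewConfig:
    """Rendering configuration for the process map.

    ``primary_view`` selects the main edge annotation; the performance
    statistic defaults to the median (robust to the long upper tails of
    administrative waiting times).  ``mixed`` adds the other view's value as
    a secondary, smaller-font label.  ``path_zoom``/``activity_zoom`` are the
    importance-zoom fractions (default: 80% of paths, all activities).
    ``edge_frequency_mode`` chooses between case-coverage percentages
    (default) and raw occurrence counts for frequency labels.
    """

    primary_view: str = "frequency"
    performance_statistic: str = "median"
    mixed: bool = True
    path_zoom: float = 0.8
    activity_zoom: float = 1.0
    edge_frequency_mode: str = "coverage"

    def validate(self) -> None:
        if self.primary_view not in ("frequency", "performance"):
            raise ValueError(f"unknown primary_view {self.primary_view!r}")
        if self.performance_statistic not in STATISTICS:
            raise ValueError(f"unknown statistic {self.performance_statistic!r}")
        if not (0.0 <= self.path_zoom <= 1.0 and 0.0 <= self.activity_zoom <= 1.0):
            raise ValueError("zoom fractions must be in [0, 1]")
        if self.edge_frequency_mode not in ("coverage", "occurrences"):
            raise ValueError(f"unknown edge_frequency_mode {self.edge_frequency_mode!r}")


def mine_map(log: EventLog) -> ProcessMap:
    """Mine the directly-follows map of an event log.

    Per-edge day gaps are ``date(target) - date(source)``; a gap of zero
    means both activities completed on the same calendar day (rendered as
    "instant").  First and last activities of each trace feed the dashed
    start/end markers.
    """
    if not log.traces:
        raise ValueError("cannot mine an empty event log")
    pmap = ProcessMap(n_cases=log.n_cases)
    for cid, trace in log.traces.items():
        seen_acts: set[str] = set()
        seen_edges: set[tuple[str, str]] = set()
        for e in trace:
            st = pmap.activities.setdefault(e.activity, ActivityStats())
            st.occurrences += 1
            if e.activity not in seen_acts:
                st.case_coverage += 1
                seen_acts.add(e.activity)
        first, last = trace[0].activity, trace[-1].activity
        pmap.start_counts[first] = pmap.start_counts.get(first, 0) + 1
        pmap.end_counts[last] = pmap.end_counts.get(last, 0) + 1
        for a, b in zip(trace, trace[1:]):
            gap = (b.date - a.date).days
            assert gap >= 0, f"negative gap in trace {cid}"
            edge = (a.activity, b.activity)
            es = pmap.edges.setdefault(edge, EdgeStats())
            es.occurrences += 1
            es.gaps.append(gap)
            if edge not in seen_edges:
                es.case_coverage += 1
                seen_edges.add(edge)
    return pmap


def edge_statistic(
    pmap: ProcessMap, edge: tuple[str, str], statistic: str = "median"
) -> float:
    """Performance statistic (days) of one edge's gap multiset."""
    if edge not in pmap.edges:
        raise KeyError(f"unknown edge {edge!r}")
    return pmap.edges[edge].statistic(statistic)


def _ranked_activities(pmap: ProcessMap) -> list[str]:
    return sorted(pmap.activities, key=lambda a: (-pmap.activities[a].case_coverage, a))


def _ranked_edges(
    pmap: ProcessMap, within: set[str]
) -> list[tuple[str, str]]:
    cand = [e for e in pmap.edges if e[0] in within and e[1] in within]
    return sorted(cand, key=lambda e: (-pmap.edges[e].occurrences, e))


def _deficiency(
    kept_acts: set[str],
    kept_edges: set[tuple[str, str]],
    pmap: ProcessMap,
) -> int:
    """Number of unmet reachability requirements: each kept activity must be
    reachable from the artificial start and co-reachable to the artificial
    end (start/end markers count as connectors)."""
    g = nx.DiGraph()
    g.add_node("__start__")
    g.add_node("__end__")
    g.add_nodes_from(kept_acts)
    g.add_edges_from(kept_edges)
    for a, c in pmap.start_counts.items():
        if a in kept_acts and c > 0:
            g.add_edge("__start__", a)
    for a, c in pmap.end_counts.items():
        if a in kept_acts and c > 0:
            g.add_edge(a, "__end__")
    from_start = nx.descendants(g, "__start__")
    to_end = nx.ancestors(g, "__end__")
    return sum(a not in from_start for a in kept_acts) + sum(
        a not in to_end for a in kept_acts
    )


def zoom(pmap: ProcessMap, f_p: float = 0.8, f_a: float = 1.0) -> ProcessMap:
    """Importance zoom: keep the top ``ceil(f_a * |A|)`` activities by case
    coverage and, among edges between kept activities, the top
    ``ceil(f_p * |E|)`` by occurrences (ties broken by label), then greedily
    re-add the highest-ranked dropped edges until no kept activity is
    disconnected from the start or the end of the process.

    The result is always a sub-map of the input; ``zoom(map, 1, 1)`` is the
    identity.
    """
    if not (0.0 <= f_p <= 1.0 and 0.0 <= f_a <= 1.0):
        raise ValueError("zoom fractions must be in [0, 1]")
    acts_ranked = _ranked_activities(pmap)
    n_keep = math.ceil(f_a * len(acts_ranked))
    kept_acts = set(acts_ranked[:n_keep])
    cand = _ranked_edges(pmap, kept_acts)
    k = math.ceil(f_p * len(cand))
    kept_edges = set(cand[:k])
    dropped = cand[k:]

    # Repair phase 1: greedily add the best-ranked dropped edge (between kept
    # activities) that strictly reduces the number of unmet start/end
    # reachability requirements.
    deficiency = _deficiency(kept_acts, kept_edges, pmap)
    while deficiency > 0 and dropped:
        for e in dropped:
            trial = _deficiency(kept_acts, kept_edges | {e}, pmap)
            if trial < deficiency:
                kept_edges.add(e)
                dropped.remove(e)
                deficiency = trial
                break
        else:
            break  # no single edge between kept activities helps

    # Repair phase 2: a tight activity zoom can leave kept activities with no
    # connecting edges among themselves at all.  Reconnect each deficient
    # activity through the full map, re-adding the traversed dropped edges
    # together with their endpoint activities (every mined activity lies on
    # some start-to-end walk, so these paths always exist).
    if deficiency > 0:
        full = nx.DiGraph()
        full.add_nodes_from(pmap.activities)
        for e in sorted(pmap.edges, key=lambda e: (-pmap.edges[e].occurrences, e)):
            full.add_edge(*e)
        for a, c in sorted(pmap.start_counts.items()):
            if c > 0:
                full.add_edge("__start__", a)
        for a, c in sorted(pmap.end_counts.items()):
            if c > 0:
                full.add_edge(a, "__end__")
        for a in acts_ranked:
            if a not in kept_acts:
                continue
            while _deficiency(kept_acts, kept_edges, pmap) > 0:
                sub = nx.DiGraph()
                sub.add_nodes_from(("__start__", "__end__"))
                sub.add_nodes_from(kept_acts)
                sub.add_edges_from(kept_edges)
                for x, c in pmap.start_counts.items():
                    if x in kept_acts and c > 0:
                        sub.add_edge("__start__", x)
                for x, c in pmap.end_counts.items():
                    if x in kept_acts and c > 0:
                        sub.add_edge(x, "__end__")
                if a in nx.descendants(sub, "__start__") and a in nx.ancestors(
                    sub, "__end__"
                ):
                    break
                for src, dst in (("__start__", a), (a, "__end__")):
                    path = nx.shortest_path(full, src, dst)
                    for u, v in zip(path, path[1:]):
                        if u != "__start__" and v != "__end__":
                            kept_acts.update((u, v))
                            kept_edges.add((u, v))

    return ProcessMap(
        n_cases=pmap.n_cases,
        activities={a: replace(pmap.activities[a]) for a in kept_acts},
        edges={e: replace(pmap.edges[e], gaps=list(pmap.edges[e].gaps)) for e in kept_edges},
        start_counts={a: c for a, c in pmap.start_counts.items() if a in kept_acts},
        end_counts={a: c for a, c in pmap.end_counts.items() if a in kept_acts},
    )


# ---------------------------------------------------------------------------
# Rendering


def _fmt_pct(pct: float) -> str:
    s = f"{pct:.1f}"
    return (s[:-2] if s.endswith(".0") else s) + "%"


def _fmt_days(v: float) -> str:
    if v == 0:
        return "instant"
    return f"{v:g} d"


def _pen_width(weight: float, wmax: float) -> float:
    if wmax <= 0:
        return 1.0
    return round(0.8 + 3.4 * weight / wmax, 2)


def render_dot(pmap: ProcessMap, view: ViewConfig | None = None) -> str:
    """Emit the map as DOT text.

    One box per activity labeled with its name and case-coverage percentage;
    solid arrows labeled with the primary-view value (plus the secondary one
    in a smaller font when ``mixed``); dashed arrows from/to small start/end
    markers; pen width scales monotonically with the primary edge weight;
    "instant" replaces a zero-day performance value.
    """
    view = view or ViewConfig()
    view.validate()
    freq_primary = view.primary_view == "frequency"
    stat = view.performance_statistic

    def freq_label(edge: tuple[str, str]) -> str:
        if view.edge_frequency_mode == "coverage":
            return _fmt_pct(pmap.edge_coverage_pct(edge))
        return str(pmap.edges[edge].occurrences)

    def perf_label(edge: tuple[str, str]) -> str:
        return _fmt_days(pmap.edges[edge].statistic(stat))

    def weight(edge: tuple[str, str]) -> float:
        es = pmap.edges[edge]
        if freq_primary:
            return es.case_coverage if view.edge_frequency_mode == "coverage" else es.occurrences
        return es.statistic(stat)

    wmax = max((weight(e) for e in pmap.edges), default=0.0)
    cmax = max((s.case_coverage for s in pmap.activities.values()), default=1)

    lines = [
        "digraph care_pathway {",
        "  rankdir=TB;",
        '  node [shape=box, style="rounded,filled", fontname="Helvetica"];',
        '  edge [fontname="Helvetica"];',
        '  __start__ [shape=circle, label="", width=0.2, fillcolor=black, style=filled];',
        '  __end__ [shape=doublecircle, label="", width=0.15, fillcolor=black, style=filled];',
    ]
    for a in sorted(pmap.activities):
        shade = 1 + round(7 * pmap.activities[a].case_coverage / max(cmax, 1))
        lines.append(
            f'  "{a}" [label="{a}\\n{_fmt_pct(pmap.activity_coverage_pct(a))}", '
            f'fillcolor="/blues9/{min(shade, 9)}"];'
        )
    for a in sorted(pmap.start_counts):
        lines.append(
            f'  __start__ -> "{a}" [style=dashed, label="{pmap.start_counts[a]}"];'
        )
    for a in sorted(pmap.end_counts):
        lines.append(
            f'  "{a}" -> __end__ [style=dashed, label="{pmap.end_counts[a]}"];'
        )
    for edge in sorted(pmap.edges):
        primary = freq_label(edge) if freq_primary else perf_label(edge)
        if view.mixed:
            secondary = perf_label(edge) if freq_primary else freq_label(edge)
            label = (
                f'<{primary}<BR/><FONT POINT-SIZE="9">{secondary}</FONT>>'
            )
        else:
            label = f'"{primary}"'
        pw = _pen_width(weight(edge), wmax)
        lines.append(
            f'  "{edge[0]}" -> "{edge[1]}" [label={label}, penwidth={pw}];'
        )
    lines.append("}")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# JSON serialization


def map_to_json(pmap: ProcessMap) -> str:
    return json.dumps(
        {
            "n_cases": pmap.n_cases,
            "activities": {
                a: {"occurrences": s.occurrences, "case_coverage": s.case_coverage}
                for a, s in sorted(pmap.activities.items())
            },
            "edges": [
                {
                    "source": s,
                    "target": t,
                    "occurrences": st.occurrences,
                    "case_coverage": st.case_coverage,
                    "gaps": st.gaps,
                }
                for (s, t), st in sorted(pmap.edges.items())
            ],
            "start_counts": dict(sorted(pmap.start_counts.items())),
            "end_counts": dict(sorted(pmap.end_counts.items())),
        },
        indent=1,
    )


def map_from_json(text: str) -> ProcessMap:
    d = json.loads(text)
    return ProcessMap(
        n_cases=d["n_cases"],
        activities={
            a: ActivityStats(s["occurrences"], s["case_coverage"])
            for a, s in d["activities"].items()
        },
        edges={
            (e["source"], e["target"]): EdgeStats(
                e["occurrences"], e["case_coverage"], list(e["gaps"])
            )
            for e in d["edges"]
        },
        start_counts=dict(d["start_counts"]),
        end_counts=dict(d["end_counts"]),
    )
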