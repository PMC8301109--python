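"""Synthetic telemetry generator with known ground truth.

Emulates a year-long radio-tracking campaign on a narrow wetland site:
24 collared animals (12 females, 12 males), one 3-day survey per month for
12 months, fixes at 1-2 h intervals, with uneven per-individual retention.
Movement is a discrete-time two-state (rest/move) correlated random walk:
the active state draws heavy-tailed lognormal speeds, the resting state is
stationary, and headings persist with von Mises turning noise. The site is
an elongated rectangle oriented NE-SW, with reflective boundaries, so step
bearings concentrate along the long axis. Planted associations steer
designated pairs toward designated habitat patches in designated months by
blending the walk heading with the bearing to a shared target patch; these
associations are the recoverable ground truth for the downstream
co-occurrence and component-plane analyses.

Everything is driven by one seeded generator: identical (seed, config)
yield bit-identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .io import HABITAT_LABELS, VEGETATION_LABELS, HabitatMap

#: Monthly average water temperature (deg C), survey months 1..12
#: (October through September of a temperate coastal wetland).
REFERENCE_WATER_TEMPS = (14.2, 9.1, 5.0, 3.2, 4.1, 7.8,
                         12.9, 17.8, 21.5, 24.9, 26.1, 22.0)

REFERENCE_SEED = 20150

#: Start of survey round 1 (fixes stamped from here; round r adds r-1 months).
REFERENCE_START = pd.Timestamp("2015-10-05 00:00:00")


@dataclass(frozen=True)
class SiteExtent:
    """Rotated rectangular site: a long axis at a compass bearing.

    The local frame has u along the long axis in [0, length] and v across
    it in [0, width]; the default bearing of 45 degrees points the long
    axis NE-SW.
    """
    center: tuple[float, float] = (0.0, 0.0)
    length: float = 6900.0
    width: float = 400.0
    bearing_deg: float = 45.0

    def __post_init__(self) -> None:
        if self.length <= 0 or self.width <= 0:
            raise ValueError("extent dimensions must be positive")

    def _axes(self) -> tuple[np.ndarray, np.ndarray]:
        b = math.radians(self.bearing_deg)
        eu = np.array([math.sin(b), math.cos(b)])       # along long axis
        ev = np.array([math.cos(b), -math.sin(b)])      # across
        return eu, ev

    def to_world(self, u, v):
        eu, ev = self._axes()
        u = np.asarray(u, dtype=float) - self.length / 2
        v = np.asarray(v, dtype=float) - self.width / 2
        x = self.center[0] + u * eu[0] + v * ev[0]
        y = self.center[1] + u * eu[1] + v * ev[1]
        return x, y

    def to_local(self, x, y):
        eu, ev = self._axes()
        dx = np.asarray(x, dtype=float) - self.center[0]
        dy = np.asarray(y, dtype=float) - self.center[1]
        u = dx * eu[0] + dy * eu[1] + self.length / 2
        v = dx * ev[0] + dy * ev[1] + self.width / 2
        return u, v

    @property
    def area(self) -> float:
        return self.length * self.width


@dataclass(frozen=True)
class AssociationRule:
    """Planted attraction: designated pairs of a class head for a habitat.

    ``strength`` s blends the walk heading with the bearing to the pair's
    target patch with weight s / (1 + s); 0 disables the rule.
    """
    pair_class: str               # "FM", "FF" or "MM"
    habitat: str                  # habitat label of the target patches
    months: tuple[int, ...]       # survey rounds in which the rule is active
    strength: float = 3.0
    n_pairs: int = 3
    #: days of the round (1-based) on which the rule applies; lets a plan
    #: time-share a habitat within each survey round
    days: tuple[int, ...] = (1, 2, 3)

    def __post_init__(self) -> None:
        if self.pair_class not in ("FM", "FF", "MM"):
            raise ValueError(f"bad pair class {self.pair_class!r}")
        if self.habitat not in HABITAT_LABELS:
            raise ValueError(f"bad habitat label {self.habitat!r}")
        if self.strength < 0:
            raise ValueError("strength must be >= 0")


#: Planted associations of the reference dataset: year-round different-sex
#: pair bonds on tall grassland, communal same-sex gatherings on the
#: floating-leaved hydrophyte beds (distinct patches per class, rotating
#: monthly so each class covers the habitat map-wide).
REFERENCE_PLAN = (
    AssociationRule("FM", "TG", months=tuple(range(1, 13)),
                    strength=5.0, n_pairs=3, days=(1, 2, 3)),
    AssociationRule("FF", "FL", months=tuple(range(1, 13)), strength=5.0,
                    n_pairs=4, days=(1, 2, 3)),
    AssociationRule("MM", "FL", months=tuple(range(1, 13)), strength=5.0,
                    n_pairs=4, days=(1, 2, 3)),
)


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = REFERENCE_SEED
    n_females: int = 12
    n_males: int = 12
    extent: SiteExtent = field(default_factory=SiteExtent)
    n_rounds: int = 12
    days_per_round: int = 3
    fix_interval: tuple[float, float] = (1.0, 2.0)   # hours
    start: pd.Timestamp = REFERENCE_START
    # two-state speed model (m/h); rest speed 0 = stationary rest
    p_move: float = 0.45
    state_persistence: float = 0.8
    move_logmu: float = 5.45
    move_logsigma: float = 0.85
    rest_speed: float = 0.0
    turn_kappa: float = 4.0       # forward-biased turning concentration
    association_plan: tuple[AssociationRule, ...] = REFERENCE_PLAN
    linger_radius: float = 100.0  # m; within this of the target, slow down
    linger_factor: float = 0.25   # speed multiplier while lingering
    linger_step_max: float = 120.0  # m; cap on a lingering step
    sortie_prob: float = 0.12     # chance a lingering step is a full-speed sortie
    p_move_directed: float = 0.70  # activity level while gathered/directed
    travel_speed_factor: float = 3.0  # directed travel is fast and brief
    home_strength: float = 1.0    # home-range bias for undirected movement
    # den sites avoid the habitats used for gatherings (e.g. open-water
    # floating vegetation): no home center within this long-axis distance
    # of a planted-habitat patch centroid
    home_exclusion_m: float = 250.0
    # per-individual fix retention drawn uniformly from this range
    keep_prob_range: tuple[float, float] = (0.15, 0.50)
    jitter_minutes: float = 10.0  # per-individual fix-time jitter

    def __post_init__(self) -> None:
        if not (0 <= self.p_move <= 1 and 0 <= self.state_persistence <= 1):
            raise ValueError("probabilities must be in [0, 1]")
        if not (0 <= self.keep_prob_range[0] <= self.keep_prob_range[1] <= 1):
            raise ValueError("keep_prob_range must be within [0, 1]")
        if self.n_females + self.n_males == 0:
            raise ValueError("empty population")
        if self.extent.area <= 0:
            raise ValueError("extent area must be positive")


@dataclass
class SimulationTruth:
    """Ground truth emitted alongside the fixes."""
    rules: list[dict]                    # planted rules with member pair ids
    keep_prob: dict[str, float]          # per-individual retention
    move_fraction: dict[str, float]      # realized active-state fraction
    cooccurrence_counts: pd.DataFrame    # month_index, pair_class, count (250 m, pre-dropout)

    def to_json(self, path) -> None:
        payload = {
            "rules": self.rules,
            "keep_prob": self.keep_prob,
            "move_fraction": self.move_fraction,
            "cooccurrence_counts":
                self.cooccurrence_counts.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def generate_habitat_map(config: SimulationConfig) -> HabitatMap:
    """Patch mosaic on the site: vegetation strips tiling the long axis,
    plus land-cover patches (road strip, open areas, one structure) overlaid.

    Deterministic for a fixed seed; every one of the 8 labels occurs in at
    least one patch; vegetation strips never overlap each other.
    """
    ext = config.extent
    n_strips = max(10, int(ext.length // 500))
    if ext.length < 50 * len(VEGETATION_LABELS) or ext.width < 40:
        raise ValueError("extent too small to place all habitat labels")
    rng = np.random.default_rng(config.seed + 101)

    # vegetation strips: random widths; the wetland's defining covers
    # (floating-leaved beds and tall grassland) recur along the site while
    # the drier covers fill the rest
    widths = rng.dirichlet(np.full(n_strips, 60.0)) * ext.length
    edges = np.concatenate([[0.0], np.cumsum(widths)])
    edges[-1] = ext.length
    # periodic mosaic: open-water beds (FL) every fourth strip, tall
    # grassland between them, drier covers cycling through the gaps -- so
    # the recurring wetland covers span the whole site and every dry strip
    # borders both an FL and a TG strip
    filler = ("XHV", "HHV", "HWV")
    labels: list[str] = []
    nf = 0
    for i in range(n_strips):
        if i % 4 == 0:
            labels.append("FL")
        elif i % 2 == 0:
            labels.append("TG")
        else:
            labels.append(filler[nf % 3])
            nf += 1
    # guarantee coverage on very small sites
    for i, lab in enumerate(VEGETATION_LABELS):
        if lab not in labels:
            labels[i] = lab

    def rect(u0, u1, v0, v1) -> Polygon:
        us = [u0, u1, u1, u0]
        vs = [v0, v0, v1, v1]
        x, y = ext.to_world(np.array(us), np.array(vs))
        return Polygon(zip(x, y))

    patches: list[tuple[str, Polygon]] = []
    for i in range(n_strips):
        patches.append((labels[i], rect(edges[i], edges[i + 1], 0, ext.width)))

    # land cover, overlapping vegetation (allowed): a crossing road, open
    # areas, one artificial structure -- all full-width slices of the long
    # axis (nothing loads on the cross-axis coordinate), and all placed on
    # the drier strips: open ground, roads and structures do not overlay
    # grassland or open-water vegetation beds
    planted = {r.habitat for r in config.association_plan}
    host = [i for i in range(n_strips) if labels[i] not in planted]
    if not host:
        host = list(range(n_strips))

    def slice_in_host(du: float) -> tuple[float, float]:
        # anchored at the grassland-adjacent end of the host strip: open
        # ground, roads and structures border the dry grassland rather
        # than the open-water beds
        i = host[int(rng.integers(len(host)))]
        lo, hi = edges[i], edges[i + 1]
        du = min(du, hi - lo)
        margin = min(50.0, (hi - lo - du) / 2)
        tg_left = i > 0 and labels[i - 1] == "TG"
        if tg_left:
            u0 = lo + margin
        else:
            u0 = hi - margin - du
        return float(u0), float(u0 + du)

    u0, u1 = slice_in_host(80.0)
    patches.append(("R", rect(u0, u1, 0, ext.width)))
    for _ in range(3):
        u0, u1 = slice_in_host(rng.uniform(0.03, 0.08) * ext.length)
        patches.append(("OA", rect(u0, u1, 0, ext.width)))
    u0, u1 = slice_in_host(100.0)
    patches.append(("AS", rect(u0, u1, 0, ext.width)))
    return HabitatMap(tuple(patches))


def _home_slots(config: SimulationConfig, hmap: HabitatMap,
                n: int) -> list[float]:
    """Evenly spaced den positions along the long axis, skipping exclusion
    zones around the patches targeted by the association plan."""
    ext = config.extent
    excl: list[tuple[float, float]] = []
    for rule in config.association_plan:
        cents = _patch_centroids(hmap, rule.habitat)
        cu, _ = ext.to_local(cents[:, 0], cents[:, 1])
        for u in np.atleast_1d(cu):
            excl.append((u - config.home_exclusion_m,
                         u + config.home_exclusion_m))
    # merge into disjoint allowed segments
    excl.sort()
    merged: list[list[float]] = []
    for lo, hi in excl:
        if merged and lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    allowed: list[tuple[float, float]] = []
    cursor = 0.0
    for lo, hi in merged:
        if lo > cursor:
            allowed.append((cursor, min(lo, ext.length)))
        cursor = max(cursor, hi)
    if cursor < ext.length:
        allowed.append((cursor, ext.length))
    total = sum(hi - lo for lo, hi in allowed)
    if total < n * 25.0:   # exclusion leaves too little room: ignore it
        allowed = [(0.0, ext.length)]
        total = ext.length
    slots = []
    targets = (np.arange(n) + 0.5) / n * total
    seg_iter = iter(allowed)
    lo, hi = next(seg_iter)
    offset = 0.0
    for t in targets:
        while t > offset + (hi - lo):
            offset += hi - lo
            lo, hi = next(seg_iter)
        slots.append(float(lo + (t - offset)))
    return slots


def _patch_centroids(hmap: HabitatMap, label: str) -> np.ndarray:
    cents = [np.array(p.centroid.coords[0])
             for lab, p in hmap.patches if lab == label]
    if not cents:
        raise ValueError(f"habitat map has no {label!r} patch")
    return np.array(cents)


def _assign_pairs(config: SimulationConfig, rng: np.random.Generator,
                  female_ids: list[str], male_ids: list[str]) -> list[dict]:
    """Draw disjoint member pairs for each association rule."""
    free = {"F": list(female_ids), "M": list(male_ids)}
    assignments = []
    for rule in config.association_plan:
        pairs = []
        for _ in range(rule.n_pairs):
            s1, s2 = rule.pair_class[0], rule.pair_class[1]
            if len(free[s1]) < 1 or len(free[s2]) < (2 if s1 == s2 else 1):
                break
            a = free[s1].pop(int(rng.integers(len(free[s1]))))
            b = free[s2].pop(int(rng.integers(len(free[s2]))))
            pairs.append((a, b))
        assignments.append({"rule": rule, "pairs": pairs})
    return assignments


def simulate_trajectories(config: SimulationConfig,
                          hmap: HabitatMap
                          ) -> tuple[pd.DataFrame, SimulationTruth]:
    """Run the two-state correlated random walk over the survey calendar.

    Returns the emitted fix table (post-dropout) and the simulation truth.
    """
    ext = config.extent
    rng = np.random.default_rng(config.seed)
    female_ids = [f"F{i + 1:02d}" for i in range(config.n_females)]
    male_ids = [f"M{i + 1:02d}" for i in range(config.n_males)]
    ids = female_ids + male_ids
    sexes = {i: ("F" if i in female_ids else "M") for i in ids}

    # fix retention drawn once, then dealt round-robin over the shuffled
    # roster so no subgroup of the population is starved of observations
    # by the luck of the draw
    draws = sorted(rng.uniform(*config.keep_prob_range, size=len(ids)),
                   reverse=True)
    # territorial spacing: home centers spread along the long axis, sexes
    # alternating, as in the species' male-female colony structure; the
    # alternation also means persistent contacts between range neighbors
    # are different-sex, not a random mix
    fshuf = list(female_ids)
    mshuf = list(male_ids)
    rng.shuffle(fshuf)
    rng.shuffle(mshuf)
    # strict F M F M alternation: every pair of range neighbors is a
    # different-sex pair, so persistent neighbor contacts never plant a
    # spurious same-sex association anywhere
    order = [ind for pair in zip(fshuf, mshuf) for ind in pair]
    order += fshuf[len(mshuf):] + mshuf[len(fshuf):]
    assignments = _assign_pairs(config, rng, female_ids, male_ids)
    roles: list[list[str]] = [
        [ind for pair in asg["pairs"] for ind in pair] for asg in assignments]
    in_role = {ind for role in roles for ind in role}
    roles.append([ind for ind in order if ind not in in_role])
    keep_prob: dict[str, float] = {}
    di = 0
    for k in range(max(len(role) for role in roles) if roles else 0):
        for role in roles:
            if k < len(role):
                keep_prob[role[k]] = float(draws[di])
                di += 1
    # dens sit away from the gathering habitats (see _home_slots): a den
    # wedged against a gathering patch would bridge its owner's incidental
    # contacts onto that patch's surroundings
    home_u = {ind: u for ind, u in
              zip(order, _home_slots(config, hmap, len(order)))}
    # staggered across the width so range neighbors sit diagonal to each
    # other, beyond casual contact range
    home_v = {ind: float(np.clip(ext.width * (0.25 + 0.5 * (j % 2))
                                 + rng.normal(0, ext.width * 0.08),
                                 0.1 * ext.width, 0.9 * ext.width))
              for j, ind in enumerate(order)}
    # per (individual, active month) -> shared target patch centroid + strength
    attract: dict[tuple[str, int], tuple[np.ndarray, float]] = {}
    rules_truth = []
    home_xy = {}
    for ind in ids:
        hx, hy = ext.to_world(home_u[ind], home_v[ind])
        home_xy[ind] = (float(hx), float(hy))

    # Each gathering group claims a distinct patch of its rule's habitat
    # (claims shared across rules on the same habitat, so two classes
    # never co-locate), then the groups of a habitat rotate over that
    # habitat's claimed patches month by month. Over the year every group
    # visits every claimed patch, so each class's incidence covers the
    # habitat map-wide, while the monthly rotation keeps the groups on
    # distinct patches at all times.
    claims: dict[str, list[dict]] = {}
    for asg in assignments:
        rule: AssociationRule = asg["rule"]
        cents = _patch_centroids(hmap, rule.habitat)
        used = {c["patch"] for c in claims.get(rule.habitat, [])}
        # same-sex pairs gather communally (every internal pairing of a
        # same-sex group is of the intended class, so group size multiplies
        # the planted signal quadratically); different-sex pairs stay
        # solitary, because any third lingering animal would form a
        # persistent wrong-class dyad at the patch
        size = 1 if rule.pair_class == "FM" else max(1, rule.n_pairs)
        chunks = [asg["pairs"][i:i + size]
                  for i in range(0, len(asg["pairs"]), size)]
        for chunk in chunks:
            members = [ind for pair in chunk for ind in pair]
            mid_u = float(np.mean([home_u[i] for i in members]))
            mid_v = float(np.mean([home_v[i] for i in members]))
            mx, my = ext.to_world(mid_u, mid_v)
            d = np.hypot(cents[:, 0] - mx, cents[:, 1] - my)
            if len(used) < len(cents):
                d = np.where(np.isin(np.arange(len(cents)), list(used)),
                             np.inf, d)
            ci = int(np.argmin(d))
            used.add(ci)
            claims.setdefault(rule.habitat, []).append(
                {"patch": ci, "members": members, "rule": rule})
        rules_truth.append({
            "pair_class": rule.pair_class, "habitat": rule.habitat,
            "months": list(rule.months), "days": list(rule.days),
            "strength": rule.strength,
            "pairs": [list(p) for p in asg["pairs"]],
        })
    for habitat, groups in claims.items():
        cents = _patch_centroids(hmap, habitat)
        patch_ring = [g["patch"] for g in groups]
        # unclaimed patches of the habitat join the rotation so the
        # association covers every patch of the label over the year
        patch_ring += sorted(set(range(len(cents))) - set(patch_ring))
        for b, g in enumerate(groups):
            rule = g["rule"]
            if rule.strength == 0:
                continue   # zero attraction: members stay ordinary residents
            for m in rule.months:
                target = cents[patch_ring[(b + m) % len(patch_ring)]]
                for ind in g["members"]:
                    attract[(ind, m)] = (target, rule.strength, rule.days)

    hours = config.days_per_round * 24.0
    lo, hi = config.fix_interval
    all_rows = []
    truth_positions = []   # (month, step_index, individual, x, y) pre-dropout
    move_steps = {i: 0 for i in ids}
    total_steps = {i: 0 for i in ids}

    for r in range(1, config.n_rounds + 1):
        t0 = config.start + pd.DateOffset(months=r - 1)
        gaps = []
        t = 0.0
        while t < hours:
            g = float(rng.uniform(lo, hi))
            gaps.append(g)
            t += g
        times_h = np.concatenate([[0.0], np.cumsum(gaps)])[:len(gaps)]

        for ind in ids:
            jit = rng.uniform(-config.jitter_minutes, config.jitter_minutes,
                              size=len(times_h)) / 60.0
            rstart = attract.get((ind, r))
            if rstart is not None and 1 not in rstart[2]:
                rstart = None      # gathers later in the round: starts at home
            if rstart is not None:
                # gathering from day 1: the member is already by its patch;
                # the move there happened outside the survey window
                x = float(rstart[0][0] + rng.normal(0, 50))
                y = float(rstart[0][1] + rng.normal(0, 50))
                uu, vv = ext.to_local(x, y)
                x, y = ext.to_world(_reflect(uu, ext.length),
                                    _reflect(vv, ext.width))
                x, y = float(x), float(y)
            else:
                u = home_u[ind] + rng.normal(0, 50)
                v = min(max(home_v[ind] + rng.normal(0, 30), 0), ext.width)
                u = min(max(u, 0.0), ext.length)
                x, y = ext.to_world(u, v)
                x, y = float(x), float(y)
            hx, hy = home_xy[ind]
            heading = float(rng.uniform(0, 2 * math.pi))
            moving = rng.random() < config.p_move
            rule_goal = attract.get((ind, r))
            keep = rng.random(len(times_h)) < keep_prob[ind]

            prev_t = times_h[0]
            for si, th in enumerate(times_h):
                dt = th - prev_t if si else 0.0
                day_of_round = int(th // 24.0) + 1
                goal = (rule_goal if rule_goal is not None
                        and day_of_round in rule_goal[2] else None)
                if si:
                    # state update
                    if rng.random() >= config.state_persistence:
                        p = (config.p_move_directed if goal is not None
                             else config.p_move)
                        moving = rng.random() < p
                    total_steps[ind] += 1
                    move_steps[ind] += int(moving)
                    if moving:
                        speed = float(rng.lognormal(config.move_logmu,
                                                    config.move_logsigma))
                    else:
                        speed = config.rest_speed
                    heading += float(rng.vonmises(0.0, config.turn_kappa))
                    if speed > 0:
                        if goal is not None:
                            tx, ty, strength = (goal[0][0], goal[0][1],
                                                goal[1])
                        else:
                            # home-range fidelity: undirected movement drifts
                            # back toward the individual's home center
                            tx, ty = hx, hy
                            strength = config.home_strength
                        gx, gy = tx - x, ty - y
                        gh = math.atan2(gx, gy)  # compass: atan2(dx, dy)
                        w = strength / (1.0 + strength)
                        vx = (1 - w) * math.sin(heading) + w * math.sin(gh)
                        vy = (1 - w) * math.cos(heading) + w * math.cos(gh)
                        heading = math.atan2(vx, vy)
                    if goal is not None and speed > 0:
                        # hurry toward the target but arrive (cap the step
                        # at the remaining distance) instead of repeatedly
                        # overshooting; once there, small wiggles keep the
                        # animal inside the patch
                        dist = math.hypot(gx, gy)
                        if dist > config.linger_radius:
                            step = min(speed * config.travel_speed_factor * dt,
                                       0.9 * dist)
                        elif rng.random() < config.sortie_prob:
                            # brief full-speed sortie away from the patch;
                            # the goal bias brings the animal straight back
                            step = speed * dt
                        else:
                            step = min(speed * config.linger_factor * dt,
                                       config.linger_step_max)
                    else:
                        step = speed * dt
                    nx = x + step * math.sin(heading)
                    ny = y + step * math.cos(heading)
                    # reflective boundaries in the local frame
                    uu, vv = ext.to_local(nx, ny)
                    uu = _reflect(uu, ext.length)
                    vv = _reflect(vv, ext.width)
                    nx, ny = ext.to_world(uu, vv)
                    if step > 0 and (nx != x or ny != y):
                        heading = math.atan2(nx - x, ny - y)
                    x, y = float(nx), float(ny)
                truth_positions.append((r, si, ind, x, y))
                if keep[si]:
                    ts = t0 + pd.Timedelta(hours=th + jit[si])
                    all_rows.append({
                        "individual_id": ind, "sex": sexes[ind],
                        "timestamp": ts.floor("s"),
                        "x": x, "y": y, "survey_round": r,
                    })
                prev_t = th

    fixes = pd.DataFrame(all_rows, columns=["individual_id", "sex",
                                            "timestamp", "x", "y",
                                            "survey_round"])
    fixes = fixes.sort_values(["individual_id", "timestamp"],
                              kind="stable").reset_index(drop=True)

    truth_counts = _true_cooccurrence_counts(truth_positions, sexes,
                                             radius=250.0)
    move_fraction = {
        i: (move_steps[i] / total_steps[i]) if total_steps[i] else 0.0
        for i in ids}
    truth = SimulationTruth(rules=rules_truth, keep_prob=keep_prob,
                            move_fraction=move_fraction,
                            cooccurrence_counts=truth_counts)
    return fixes, truth


def _reflect(val: np.ndarray | float, hi: float) -> np.ndarray | float:
    """Fold a coordinate into [0, hi] by mirror reflection."""
    v = np.abs(np.asarray(val, dtype=float))
    period = 2 * hi
    v = v % period
    v = np.where(v > hi, period - v, v)
    return float(v) if np.isscalar(val) else v


def _true_cooccurrence_counts(truth_positions, sexes,
                              radius: float) -> pd.DataFrame:
    """Pre-dropout pair counts within radius, per month and pair class."""
    df = pd.DataFrame(truth_positions,
                      columns=["month", "step", "individual_id", "x", "y"])
    rows = []
    for (m, s), grp in df.groupby(["month", "step"]):
        xy = grp[["x", "y"]].to_numpy()
        inds = grp["individual_id"].to_numpy()
        n = len(grp)
        if n < 2:
            continue
        from scipy.spatial import cKDTree
        pairs = cKDTree(xy).query_pairs(r=radius, output_type="ndarray")
        for i, j in pairs:
            cls = "".join(sorted(sexes[inds[i]] + sexes[inds[j]]))
            rows.append({"month_index": int(m), "pair_class": cls})
    if not rows:
        return pd.DataFrame(columns=["month_index", "pair_class", "count"])
    counts = (pd.DataFrame(rows)
              .groupby(["month_index", "pair_class"])
              .size().rename("count").reset_index())
    return counts


def reference_temperatures() -> pd.DataFrame:
    return pd.DataFrame({"month": range(1, 13),
                         "wt": REFERENCE_WATER_TEMPS})


def reference_dataset(seed: int = REFERENCE_SEED
                      ) -> tuple[pd.DataFrame, HabitatMap, pd.DataFrame,
                                 SimulationTruth]:
    """The fixed-seed study-design dataset: 12 F + 12 M, 12 monthly 3-day
    rounds at 1-2 h fix intervals, planted associations per REFERENCE_PLAN.
    """
    config = SimulationConfig(seed=seed)
    hmap = generate_habitat_map(config)
    fixes, truth = simulate_trajectories(config, hmap)
    return fixes, hmap, reference_temperatures(), truth
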