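"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately written from the definitions, sharing no
evaluation or graph code with the package: expression evaluation is its own
recursion, rule parsing has a separate precedence-climbing oracle,
asynchronous attractors come from a hand-rolled iterative Tarjan SCC over a
directly constructed state-transition graph, and the three rule-combination
formulas are coded pointwise.
"""

from __future__ import annotations

from itertools import product

from boolmerge.logic import And, BoolExpr, Const, Not, Or, Var


# ---------------------------------------------------------------------------
# expression evaluation (independent recursion)


def oracle_eval(expr: BoolExpr, state: dict[str, int]) -> int:
    if isinstance(expr, Var):
        return int(bool(state[expr.name]))
    if isinstance(expr, Const):
        return expr.value
    if isinstance(expr, Not):
        return 0 if oracle_eval(expr.child, state) else 1
    if isinstance(expr, And):
        return int(all(oracle_eval(c, state) for c in expr.children))
    if isinstance(expr, Or):
        return int(any(oracle_eval(c, state) for c in expr.children))
    raise TypeError(expr)


def oracle_vars(expr: BoolExpr) -> set[str]:
    if isinstance(expr, Var):
        return {expr.name}
    if isinstance(expr, Const):
        return set()
    if isinstance(expr, Not):
        return oracle_vars(expr.child)
    return set().union(*(oracle_vars(c) for c in expr.children))


def all_states(names: list[str]):
    for bits in product((0, 1), repeat=len(names)):
        yield dict(zip(names, bits))


# ---------------------------------------------------------------------------
# rule-text oracle: precedence climbing (distinct from the package's
# recursive-descent parser) evaluated directly against an assignment


def oracle_eval_text(text: str, state: dict[str, int]) -> int:
    """Evaluate rule text under ``!`` > ``&`` > ``|`` without building the
    package's AST."""
    import re

    tokens = re.findall(r"[A-Za-z0-9_]+|[&|!()]", text)
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def eat():
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def atom() -> int:
        tok = eat()
        if tok == "!":
            return 1 - atom()
        if tok == "(":
            v = or_level()
            assert eat() == ")"
            return v
        if tok in ("0", "1"):
            return int(tok)
        return int(bool(state[tok]))

    def and_level() -> int:
        v = atom()
        while peek() == "&":
            eat()
            v &= atom()
        return v

    def or_level() -> int:
        v = and_level()
        while peek() == "|":
            eat()
            v |= and_level()
        return v

    result = or_level()
    assert pos == len(tokens), "trailing tokens"
    return result


# ---------------------------------------------------------------------------
# regulator signs by exhaustive flip test (from the definition)


def oracle_signs(expr: BoolExpr) -> dict[str, str]:
    names = sorted(oracle_vars(expr))
    up, down = set(), set()
    for state in all_states(names):
        for v in names:
            lo = oracle_eval(expr, {**state, v: 0})
            hi = oracle_eval(expr, {**state, v: 1})
            if lo == 0 and hi == 1:
                up.add(v)
            elif lo == 1 and hi == 0:
                down.add(v)
    out = {}
    for v in names:
        if v in up and v in down:
            out[v] = "dual"
        elif v in up:
            out[v] = "activator"
        elif v in down:
            out[v] = "inhibitor"
        else:
            out[v] = "none"
    return out


# ---------------------------------------------------------------------------
# merge formulas, pointwise


def oracle_or(rules: list[BoolExpr], state: dict[str, int]) -> int:
    return max(oracle_eval(r, state) for r in rules)


def oracle_and(rules: list[BoolExpr], state: dict[str, int]) -> int:
    return min(oracle_eval(r, state) for r in rules)


def oracle_iw(rules: list[BoolExpr], state: dict[str, int]) -> int:
    """Piecewise definition: 0 if any inhibitor (of any source rule) is ON
    in the current state, else the OR combination."""
    inhibitors = set()
    for r in rules:
        for reg, sign in oracle_signs(r).items():
            if sign in ("inhibitor", "dual"):
                inhibitors.add(reg)
    if any(state[i] for i in inhibitors):
        return 0
    return oracle_or(rules, state)


# ---------------------------------------------------------------------------
# attractors on models given as {node: BoolExpr | None}


def _step(rules: dict[str, BoolExpr | None], state: dict[str, int]):
    return {
        n: (state[n] if r is None else oracle_eval(r, state))
        for n, r in rules.items()
    }


def oracle_sync_attractors(
    rules: dict[str, BoolExpr | None],
) -> set[frozenset[tuple[tuple[str, int], ...]]]:
    """All cycles of the synchronous map, by iterating every state."""
    names = sorted(rules)
    cycles = set()
    for init in all_states(names):
        seen = {}
        cur = init
        while True:
            key = tuple(sorted(cur.items()))
            if key in seen:
                cycle_keys = list(seen)[seen[key]:]
                cycles.add(frozenset(cycle_keys))
                break
            seen[key] = len(seen)
            cur = _step(rules, cur)
    return cycles


def oracle_async_attractors(
    rules: dict[str, BoolExpr | None],
) -> set[frozenset[tuple[tuple[str, int], ...]]]:
    """Terminal SCCs of the asynchronous STG, via iterative Tarjan."""
    names = sorted(rules)
    states = [tuple(sorted(s.items())) for s in all_states(names)]

    def successors(key):
        state = dict(key)
        out = []
        for n, r in rules.items():
            if r is None:
                continue
            v = oracle_eval(r, state)
            if v != state[n]:
                out.append(tuple(sorted({**state, n: v}.items())))
        return out

    succ = {s: successors(s) for s in states}

    # iterative Tarjan
    index = {}
    low = {}
    on_stack = set()
    stack = []
    sccs = []
    counter = [0]

    for root in states:
        if root in index:
            continue
        work = [(root, 0)]
        while work:
            node, i = work.pop()
            if i == 0:
                index[node] = low[node] = counter[0]
                counter[0] += 1
                stack.append(node)
                on_stack.add(node)
            recurse = False
            for j in range(i, len(succ[node])):
                w = succ[node][j]
                if w not in index:
                    work.append((node, j + 1))
                    work.append((w, 0))
                    recurse = True
                    break
                if w in on_stack:
                    low[node] = min(low[node], index[w])
            if recurse:
                continue
            if low[node] == index[node]:
                comp = []
                while True:
                    w = stack.pop()
                    on_stack.discard(w)
                    comp.append(w)
                    if w == node:
                        break
                sccs.append(comp)
            if work:
                parent = work[-1][0]
                low[parent] = min(low[parent], low[node])
    terminal = set()
    for comp in sccs:
        members = set(comp)
        if all(t in members for s in comp for t in succ[s]):
            terminal.add(frozenset(comp))
    return terminal
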