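"""Plain-text fitting-configuration dialect.

A configuration file fully specifies a fitting run for a kinetic model, and
switching configuration files alone switches the model being fitted — no
code changes.  The dialect has five fixed sections, each introduced by a
``//`` header line; other ``//`` lines are comments:

    //FITTING PARAMETERS AND INITIAL VALUES
    <count>
    <index> <name> <initial>          (count lines)
    //CONSTRAINTS
    <lo> <hi>                         (count lines, same order)
    //DEPENDENCY RULES FOR PARAMETERS NOT FITTED
    <count>
    <name> = <expression>             (count lines)
    //EXCLUSION RULES
    <count>
    <boolean expression>              (count lines)
    //PARAMETERS WARNING (ALL EXCEPT)
    <count>
    <name>                            (count lines)

Expressions are restricted to names, numeric literals, ``+ - * / ^``,
comparisons and parentheses; the typographical variant ``^*^`` is accepted
for ``*``.  Parameter names are opaque strings mapped onto model parameters
through a per-model registry, so simulator-style names such as
``syn[0].tau1`` or ``nc[0].weight`` parse verbatim.  Warning checks apply to
all fitted parameters *except* those listed in the last section.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "ParamSpec",
    "FitConfig",
    "ModelRegistry",
    "ConfigParseError",
    "EvaluationError",
    "DependencyError",
    "Expr",
    "parse_expr",
    "parse_config",
    "serialize_config",
    "eval_exclusion",
    "apply_dependencies",
    "GEPHYRIN_REGISTRY",
    "BIEXP_REGISTRY",
    "load_builtin_config",
    "BUILTIN_CONFIGS",
]


class ConfigParseError(ValueError):
    """Malformed configuration text; the message names the offending line."""


class EvaluationError(ValueError):
    """An expression referenced a name with no bound value."""


class DependencyError(ValueError):
    """A dependency expression used a target assigned later (cycle)."""


# ---------------------------------------------------------------------------
# Expressions

_TOKEN_RE = re.compile(
    r"\s*(?:"
    r"(?P<num>(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?)"
    r"|(?P<name>[A-Za-z_][A-Za-z0-9_.\[\]]*)"
    r"|(?P<cmp><=|>=|==|!=|<|>)"
    r"|(?P<op>[-+*/^()])"
    r")"
)


def _tokenize(source: str) -> list[tuple[str, str]]:
    source = source.replace("^*^", "*")
    tokens: list[tuple[str, str]] = []
    pos = 0
    while pos < len(source):
        m = _TOKEN_RE.match(source, pos)
        if m is None:
            if source[pos:].strip() == "":
                break
            raise ConfigParseError(f"cannot tokenize expression at: {source[pos:]!r}")
        pos = m.end()
        for kind in ("num", "name", "cmp", "op"):
            text = m.group(kind)
            if text is not None:
                tokens.append((kind, text))
                break
    return tokens


class Expr:
    """A parsed restricted arithmetic/comparison expression."""

    def __init__(self, source: str) -> None:
        self.source = source.strip()
        self._tokens = _tokenize(self.source)
        self._pos = 0
        self._ast = self._comparison()
        if self._pos != len(self._tokens):
            raise ConfigParseError(
                f"trailing tokens in expression {self.source!r}"
            )

    # -- recursive descent -------------------------------------------------
    def _peek(self) -> tuple[str, str] | None:
        return self._tokens[self._pos] if self._pos < len(self._tokens) else None

    def _next(self) -> tuple[str, str]:
        tok = self._peek()
        if tok is None:
            raise ConfigParseError(f"unexpected end of expression {self.source!r}")
        self._pos += 1
        return tok

    def _comparison(self):
        left = self._arith()
        tok = self._peek()
        if tok is not None and tok[0] == "cmp":
            self._next()
            right = self._arith()
            return ("cmp", tok[1], left, right)
        return left

    def _arith(self):
        node = self._term()
        while (tok := self._peek()) is not None and tok[1] in "+-" and tok[0] == "op":
            self._next()
            node = ("bin", tok[1], node, self._term())
        return node

    def _term(self):
        node = self._factor()
        while (tok := self._peek()) is not None and tok[1] in "*/" and tok[0] == "op":
            self._next()
            node = ("bin", tok[1], node, self._factor())
        return node

    def _factor(self):
        tok = self._peek()
        if tok is not None and tok == ("op", "-"):
            self._next()
            return ("neg", self._factor())
        return self._power()

    def _power(self):
        base = self._atom()
        tok = self._peek()
        if tok == ("op", "^"):
            self._next()
            return ("bin", "^", base, self._factor())
        return base

    def _atom(self):
        kind, text = self._next()
        if kind == "num":
            return ("num", float(text))
        if kind == "name":
            return ("name", text)
        if (kind, text) == ("op", "("):
            node = self._comparison()
            closing = self._next()
            if closing != ("op", ")"):
                raise ConfigParseError(f"expected ')' in {self.source!r}")
            return node
        raise ConfigParseError(f"unexpected token {text!r} in {self.source!r}")

    # -- public API --------------------------------------------------------
    def names(self) -> set[str]:
        found: set[str] = set()

        def walk(node) -> None:
            if node[0] == "name":
                found.add(node[1])
            elif node[0] == "neg":
                walk(node[1])
            elif node[0] in ("bin", "cmp"):
                walk(node[2])
                walk(node[3])

        walk(self._ast)
        return found

    def evaluate(self, env: dict[str, float]) -> float | bool:
        def ev(node):
            kind = node[0]
            if kind == "num":
                return node[1]
            if kind == "name":
                try:
                    return env[node[1]]
                except KeyError:
                    raise EvaluationError(
                        f"unbound name {node[1]!r} in {self.source!r}"
                    ) from None
            if kind == "neg":
                return -ev(node[1])
            if kind == "bin":
                a, b = ev(node[2]), ev(node[3])
                op = node[1]
                if op == "+":
                    return a + b
                if op == "-":
                    return a - b
                if op == "*":
                    return a * b
                if op == "/":
                    return a / b
                return a ** b  # '^'
            # comparison
            a, b = ev(node[2]), ev(node[3])
            op = node[1]
            return {"<": a < b, "<=": a <= b, ">": a > b, ">=": a >= b,
                    "==": a == b, "!=": a != b}[op]

        return ev(self._ast)

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"Expr({self.source!r})"


def parse_expr(source: str) -> Expr:
    return Expr(source)


# ---------------------------------------------------------------------------
# Registry and config types

@dataclass(frozen=True)
class ModelRegistry:
    """Maps opaque config names onto a model's canonical parameter names."""

    model: str
    aliases: dict[str, str]
    parameters: frozenset[str]
    derived: frozenset[str] = frozenset()

    def canonical(self, name: str) -> str:
        return self.aliases.get(name, name)

    def resolves(self, name: str) -> bool:
        c = self.canonical(name)
        return c in self.parameters or c in self.derived


GEPHYRIN_REGISTRY = ModelRegistry(
    model="gephyrin",
    aliases={
        "syn[0].w": "w", "syn[0].taur": "tau_r", "syn[0].tau_r": "tau_r",
        "syn[0].taud": "tau_d", "syn[0].tau_d": "tau_d",
        "syn[0].beta": "beta", "syn[0].alphaf": "alpha_f",
        "syn[0].alpha_f": "alpha_f", "syn[0].alphab": "alpha_b",
        "syn[0].alpha_b": "alpha_b", "syn[0].geph": "geph",
        "syn[0].phi": "phi", "syn[0].h": "h", "syn[0].h1": "h1",
        "syn[0].c1": "c1", "nstim.start": "t0",
        "syn[0].nhalf": "nhalf", "syn[0].nlmax": "nlmax",
    },
    parameters=frozenset({"w", "tau_r", "tau_d", "beta", "alpha_f", "alpha_b",
                          "geph", "phi", "h", "h1", "c1", "t0"}),
    derived=frozenset({"nhalf", "nlmax"}),
)

BIEXP_REGISTRY = ModelRegistry(
    model="biexp",
    aliases={
        "syn[0].tau1": "tau1", "syn[0].tau2": "tau2",
        "nstim.start": "t_start", "nc[0].weight": "weight",
    },
    parameters=frozenset({"tau1", "tau2", "t_start", "weight"}),
)


@dataclass(frozen=True)
class ParamSpec:
    index: int
    name: str
    initial: float
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ConfigParseError(
                f"parameter {self.name!r}: bounds must satisfy lo < hi, "
                f"got [{self.lo}, {self.hi}]"
            )
        if not (self.lo <= self.initial <= self.hi):
            raise ConfigParseError(
                f"parameter {self.name!r}: initial {self.initial} outside "
                f"bounds [{self.lo}, {self.hi}]"
            )


@dataclass(frozen=True)
class FitConfig:
    params: tuple[ParamSpec, ...]
    dependencies: tuple[tuple[str, Expr], ...] = ()
    exclusions: tuple[Expr, ...] = ()
    warn_except: tuple[str, ...] = ()
    registry: ModelRegistry | None = None

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.params)

    @property
    def warn_set(self) -> tuple[str, ...]:
        """Fitted parameters subject to outlier warnings (all except listed)."""
        excluded = set(self.warn_except)
        return tuple(n for n in self.names if n not in excluded)

    def canonical(self, name: str) -> str:
        return self.registry.canonical(name) if self.registry else name


# ---------------------------------------------------------------------------
# Parsing

_SECTION_HEADERS = (
    "//FITTING PARAMETERS AND INITIAL VALUES",
    "//CONSTRAINTS",
    "//DEPENDENCY RULES FOR PARAMETERS NOT FITTED",
    "//EXCLUSION RULES",
    "//PARAMETERS WARNING (ALL EXCEPT)",
)


class _Lines:
    def __init__(self, text: str) -> None:
        self.lines = text.splitlines()
        self.pos = 0

    def next_content(self, *, allow_header: bool = False) -> tuple[int, str] | None:
        """Next non-blank, non-comment line (1-based number, stripped text)."""
        while self.pos < len(self.lines):
            lineno = self.pos + 1
            stripped = self.lines[self.pos].strip()
            self.pos += 1
            if not stripped:
                continue
            if stripped.startswith("//"):
                if stripped in _SECTION_HEADERS:
                    if allow_header:
                        return lineno, stripped
                    raise ConfigParseError(
                        f"line {lineno}: unexpected section header {stripped!r}"
                    )
                continue  # ordinary comment
            return lineno, stripped
        return None

    def expect_header(self, header: str) -> None:
        got = self.next_content(allow_header=True)
        if got is None or got[1] != header:
            where = f"line {got[0]}: {got[1]!r}" if got else "end of file"
            raise ConfigParseError(f"expected section header {header!r}, got {where}")

    def expect_count(self, what: str) -> int:
        got = self.next_content()
        if got is None:
            raise ConfigParseError(f"missing {what} count at end of file")
        lineno, text = got
        try:
            n = int(text)
        except ValueError:
            raise ConfigParseError(
                f"line {lineno}: expected {what} count, got {text!r}"
            ) from None
        if n < 0:
            raise ConfigParseError(f"line {lineno}: negative {what} count")
        return n

    def expect_line(self, what: str) -> tuple[int, str]:
        got = self.next_content()
        if got is None:
            raise ConfigParseError(f"missing {what} line: section count mismatch")
        return got


def parse_config(text: str, registry: ModelRegistry | None = None) -> FitConfig:
    """Parse configuration text into a :class:`FitConfig`.

    When a ``registry`` is given, every name used in the file must resolve to
    one of the model's parameters or derived constants.  Raises
    :class:`ConfigParseError` naming the offending line otherwise.
    """
    lines = _Lines(text)

    lines.expect_header(_SECTION_HEADERS[0])
    n_params = lines.expect_count("parameter")
    raw_params: list[tuple[int, str, float]] = []
    for i in range(n_params):
        lineno, body = lines.expect_line("parameter")
        parts = body.split()
        if len(parts) != 3:
            raise ConfigParseError(
                f"line {lineno}: expected '<index> <name> <initial>', got {body!r}"
            )
        try:
            idx = int(parts[0])
            initial = float(parts[2])
        except ValueError:
            raise ConfigParseError(f"line {lineno}: malformed parameter line {body!r}") from None
        if idx != i:
            raise ConfigParseError(
                f"line {lineno}: parameter index {idx}, expected {i} (gapless 0..n-1)"
            )
        raw_params.append((idx, parts[1], initial))

    lines.expect_header(_SECTION_HEADERS[1])
    params: list[ParamSpec] = []
    for idx, name, initial in raw_params:
        lineno, body = lines.expect_line("constraint")
        parts = body.split()
        if len(parts) != 2:
            raise ConfigParseError(
                f"line {lineno}: expected '<lo> <hi>' bounds, got {body!r}"
            )
        try:
            lo, hi = float(parts[0]), float(parts[1])
        except ValueError:
            raise ConfigParseError(f"line {lineno}: malformed bounds line {body!r}") from None
        try:
            params.append(ParamSpec(index=idx, name=name, initial=initial, lo=lo, hi=hi))
        except ConfigParseError as exc:
            raise ConfigParseError(f"line {lineno}: {exc}") from None

    lines.expect_header(_SECTION_HEADERS[2])
    n_dep = lines.expect_count("dependency")
    dependencies: list[tuple[str, Expr]] = []
    for _ in range(n_dep):
        lineno, body = lines.expect_line("dependency")
        target, eq, expr_src = body.partition("=")
        if not eq:
            raise ConfigParseError(
                f"line {lineno}: expected '<name> = <expression>', got {body!r}"
            )
        try:
            dependencies.append((target.strip(), Expr(expr_src)))
        except ConfigParseError as exc:
            raise ConfigParseError(f"line {lineno}: {exc}") from None

    lines.expect_header(_SECTION_HEADERS[3])
    n_exc = lines.expect_count("exclusion")
    exclusions: list[Expr] = []
    for _ in range(n_exc):
        lineno, body = lines.expect_line("exclusion")
        try:
            exclusions.append(Expr(body))
        except ConfigParseError as exc:
            raise ConfigParseError(f"line {lineno}: {exc}") from None

    lines.expect_header(_SECTION_HEADERS[4])
    n_warn = lines.expect_count("warning")
    warn_except: list[str] = []
    for _ in range(n_warn):
        _, body = lines.expect_line("warning")
        warn_except.append(body.split()[0])

    trailing = lines.next_content(allow_header=True)
    if trailing is not None:
        raise ConfigParseError(
            f"line {trailing[0]}: unexpected content after last section: {trailing[1]!r}"
        )

    config = FitConfig(
        params=tuple(params),
        dependencies=tuple(dependencies),
        exclusions=tuple(exclusions),
        warn_except=tuple(warn_except),
        registry=registry,
    )
    if registry is not None:
        _check_names(config, registry)
    return config


def _check_names(config: FitConfig, registry: ModelRegistry) -> None:
    declared = {registry.canonical(n) for n in config.names}
    dep_targets = {registry.canonical(t) for t, _ in config.dependencies}
    known = declared | dep_targets | registry.parameters | registry.derived
    for p in config.params:
        if not registry.resolves(p.name):
            raise ConfigParseError(
                f"parameter {p.name!r} does not resolve in model "
                f"{registry.model!r}"
            )
    for target, expr in config.dependencies:
        for name in {target} | expr.names():
            if registry.canonical(name) not in known:
                raise ConfigParseError(
                    f"dependency name {name!r} does not resolve in model "
                    f"{registry.model!r}"
                )
    for expr in config.exclusions:
        for name in expr.names():
            if registry.canonical(name) not in known:
                raise ConfigParseError(
                    f"exclusion name {name!r} does not resolve in model "
                    f"{registry.model!r}"
                )
    for name in config.warn_except:
        if registry.canonical(name) not in declared:
            raise ConfigParseError(
                f"warning-section name {name!r} is not a fitted parameter"
            )


def _fmt(x: float) -> str:
    return format(x, "g")


def serialize_config(config: FitConfig) -> str:
    """Canonical text form; parse -> serialize -> parse is the identity."""
    out: list[str] = [_SECTION_HEADERS[0], str(len(config.params))]
    for p in config.params:
        out.append(f"{p.index} {p.name} {_fmt(p.initial)}")
    out.append(_SECTION_HEADERS[1])
    for p in config.params:
        out.append(f"{_fmt(p.lo)} {_fmt(p.hi)}")
    out.append(_SECTION_HEADERS[2])
    out.append(str(len(config.dependencies)))
    for target, expr in config.dependencies:
        out.append(f"{target} = {expr.source}")
    out.append(_SECTION_HEADERS[3])
    out.append(str(len(config.exclusions)))
    for expr in config.exclusions:
        out.append(expr.source)
    out.append(_SECTION_HEADERS[4])
    out.append(str(len(config.warn_except)))
    out.extend(config.warn_except)
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# Rule evaluation

def _canonical_env(config: FitConfig, values: dict[str, float]) -> dict[str, float]:
    env = dict(values)
    if config.registry is not None:
        for name, val in values.items():
            env.setdefault(config.registry.canonical(name), val)
    return env


def eval_exclusion(config: FitConfig, values: dict[str, float]) -> bool:
    """True if ANY exclusion rule is satisfied (the vector is rejected)."""
    env = _canonical_env(config, values)

    def lookup(name: str) -> float:
        if name in env:
            return env[name]
        c = config.canonical(name)
        if c in env:
            return env[c]
        raise EvaluationError(f"unbound name {name!r} in exclusion rule")

    for expr in config.exclusions:
        local = {n: lookup(n) for n in expr.names()}
        if bool(expr.evaluate(local)):
            return True
    return False


def apply_dependencies(config: FitConfig,
                       values: dict[str, float]) -> dict[str, float]:
    """Assign non-fitted parameters from their expressions, in declaration order.

    A dependency expression may reference fitted parameters, model constants
    already present in ``values``, and previously assigned targets; using a
    target declared later raises :class:`DependencyError`.
    """
    env = _canonical_env(config, values)
    pending = {config.canonical(t) for t, _ in config.dependencies}
    out = dict(values)
    for target, expr in config.dependencies:
        ctarget = config.canonical(target)
        local: dict[str, float] = {}
        for name in expr.names():
            cname = config.canonical(name)
            if cname in pending:
                raise DependencyError(
                    f"dependency {target!r} references {name!r}, which is "
                    "assigned later"
                )
            if name in env:
                local[name] = env[name]
            elif cname in env:
                local[name] = env[cname]
            else:
                raise EvaluationError(
                    f"unbound name {name!r} in dependency for {target!r}"
                )
        value = float(expr.evaluate(local))
        pending.discard(ctarget)
        env[ctarget] = value
        env[target] = value
        out[ctarget] = value
    return out


# ---------------------------------------------------------------------------
# Shipped configurations

BUILTIN_CONFIGS = ("gephyrin", "gephyrin_reduced", "biexp")


def load_builtin_config(name: str) -> FitConfig:
    """Load a shipped configuration (``gephyrin``, ``gephyrin_reduced``, ``biexp``)."""
    from importlib import resources

    if name not in BUILTIN_CONFIGS:
        raise ValueError(f"unknown builtin config {name!r}; choose from {BUILTIN_CONFIGS}")
    text = (resources.files("ipscfit") / "configs" / f"{name}.cfg").read_text()
    registry = BIEXP_REGISTRY if name == "biexp" else GEPHYRIN_REGISTRY
    return parse_config(text, registry=registry)
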