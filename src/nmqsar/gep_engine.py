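"""Gene expression programming: symbolic regression with Karva-encoded genes.

A chromosome is a fixed number of genes, each a linear string of symbols
split into a head (functions or terminals, length h) and a tail (terminals
only, length t = h·(max_arity − 1) + 1).  The tail length guarantees that
*every* head configuration decodes to a complete expression tree, so all
genetic operators are closed over valid genotypes.  Genes are decoded
breadth-first (Karva notation) and combined with a linking operator.

Fitness is the R² of the linked prediction against the activities, floored
at zero; any invalid arithmetic (division by ~0, log of a non-positive
value, overflow) invalidates the chromosome for that dataset (fitness 0)
rather than being "protected" away.  Evolution is generational
roulette-wheel selection with single-elite cloning plus the classical
operator suite: point mutation, inversion, IS/RIS/gene transposition, one-
and two-point recombination, and whole-gene recombination.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np

from nmqsar.validation import mae as _mae

_EPS_DIV = 1e-12


# ---------------------------------------------------------------------------
# function set
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FunctionSet:
    """Operator symbols with arities, plus the terminal alphabet X0…X(p−1)."""

    operators: dict[str, int] = field(
        default_factory=lambda: {"+": 2, "-": 2, "*": 2, "/": 2, "Ln": 1, "sin": 1}
    )
    n_terminals: int = 1

    def __post_init__(self):
        if self.n_terminals < 1:
            raise ValueError("need at least one terminal")
        if not self.operators:
            raise ValueError("need at least one operator")
        if any(a < 1 for a in self.operators.values()):
            raise ValueError("operator arity must be ≥ 1")

    @property
    def terminals(self) -> tuple[str, ...]:
        return tuple(f"X{i}" for i in range(self.n_terminals))

    @property
    def function_symbols(self) -> tuple[str, ...]:
        return tuple(self.operators)

    @property
    def max_arity(self) -> int:
        return max(self.operators.values())

    def arity(self, symbol: str) -> int:
        return self.operators.get(symbol, 0)

    def is_terminal(self, symbol: str) -> bool:
        return symbol not in self.operators


def _apply(symbol: str, args: list[np.ndarray]) -> np.ndarray:
    """Vectorised operator semantics; invalid entries become NaN."""
    with np.errstate(all="ignore"):
        if symbol == "+":
            out = args[0] + args[1]
        elif symbol == "-":
            out = args[0] - args[1]
        elif symbol == "*":
            out = args[0] * args[1]
        elif symbol == "/":
            denom = args[1]
            out = np.where(np.abs(denom) < _EPS_DIV, np.nan, args[0] / np.where(denom == 0, 1, denom))
        elif symbol == "Ln":
            out = np.where(args[0] > 0, np.log(np.where(args[0] > 0, args[0], 1.0)), np.nan)
        elif symbol == "sin":
            out = np.sin(args[0])
        else:
            raise ValueError(f"unknown operator {symbol!r}")
    return np.where(np.isfinite(out), out, np.nan)


# ---------------------------------------------------------------------------
# genes, chromosomes, Karva decoding
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Gene:
    """A Karva gene: head of length h, tail of length h·(max_arity−1)+1."""

    symbols: tuple[str, ...]
    head_length: int

    def __post_init__(self):
        if not 0 < self.head_length < len(self.symbols):
            raise ValueError("head length must be positive and shorter than the gene")

    @property
    def head(self) -> tuple[str, ...]:
        return self.symbols[: self.head_length]

    @property
    def tail(self) -> tuple[str, ...]:
        return self.symbols[self.head_length :]

    def validate(self, fset: FunctionSet) -> None:
        t_expected = self.head_length * (fset.max_arity - 1) + 1
        if len(self.tail) != t_expected:
            raise ValueError(f"tail length must be {t_expected}, got {len(self.tail)}")
        bad = [s for s in self.tail if not fset.is_terminal(s)]
        if bad:
            raise ValueError(f"function symbol(s) in tail: {bad}")


@dataclass(frozen=True)
class Chromosome:
    genes: tuple[Gene, ...]
    linking: str = "+"

    def __post_init__(self):
        if not self.genes:
            raise ValueError("chromosome needs at least one gene")
        h = {g.head_length for g in self.genes}
        if len(h) != 1:
            raise ValueError("all genes must share one head length")

    @property
    def head_length(self) -> int:
        return self.genes[0].head_length


class Node:
    """Expression-tree node."""

    __slots__ = ("symbol", "children")

    def __init__(self, symbol: str, children: Optional[list["Node"]] = None):
        self.symbol = symbol
        self.children = children or []

    def infix(self) -> str:
        if not self.children:
            return self.symbol
        if len(self.children) == 1:
            return f"{self.symbol}({self.children[0].infix()})"
        return f"({self.children[0].infix()}{self.symbol}{self.children[1].infix()})"

    def depth(self) -> int:
        if not self.children:
            return 1
        return 1 + max(c.depth() for c in self.children)


def decode_karva(gene: Gene, fset: FunctionSet) -> Node:
    """Breadth-first decode of a Karva gene into an expression tree.

    Symbol 0 is the root; each function node consumes the next unused
    symbols left-to-right, level by level.  Unused trailing symbols are
    simply ignored (non-coding region).
    """
    gene.validate(fset)
    syms = gene.symbols
    root = Node(syms[0])
    queue = [root]
    cursor = 1
    while queue:
        node = queue.pop(0)
        k = fset.arity(node.symbol)
        for _ in range(k):
            if cursor >= len(syms):
                raise ValueError("gene exhausted during decoding (invalid structure)")
            child = Node(syms[cursor])
            cursor += 1
            node.children.append(child)
            queue.append(child)
    return root


def encode_karva(tree: Node, fset: FunctionSet, head_length: int) -> Gene:
    """Re-encode an expression tree (breadth-first read-off) into a gene.

    The tree depth must fit the head; the tail is padded with the first
    terminal.  Inverse of :func:`decode_karva` up to non-coding symbols.
    """
    order: list[str] = []
    queue = [tree]
    while queue:
        node = queue.pop(0)
        order.append(node.symbol)
        queue.extend(node.children)
    if len([s for s in order if not fset.is_terminal(s)]) > head_length:
        raise ValueError("tree too large for the head length")
    t = head_length * (fset.max_arity - 1) + 1
    filler = fset.terminals[0]
    head = order[:head_length] + [filler] * max(0, head_length - len(order))
    rest = order[head_length:]
    tail = [s for s in rest] + [filler] * (t - len(rest))
    if any(not fset.is_terminal(s) for s in tail):
        raise ValueError("tree too deep: function symbol would land in the tail")
    return Gene(tuple(head + tail), head_length)


def evaluate_tree(tree: Node, X: np.ndarray, fset: FunctionSet) -> np.ndarray:
    """Evaluate a tree on rows of X; invalid entries are NaN, never raises.

    Terminals ``Xi`` bind to column i of X.  Division by |denominator|
    < 1e-12, Ln of a non-positive argument, and non-finite results all
    yield NaN for the affected rows.
    """
    X = np.atleast_2d(np.asarray(X, float))
    if tree.children:
        args = [evaluate_tree(c, X, fset) for c in tree.children]
        return _apply(tree.symbol, args)
    if not tree.symbol.startswith("X"):
        raise ValueError(f"unbound terminal {tree.symbol!r}")
    idx = int(tree.symbol[1:])
    if idx >= X.shape[1]:
        raise ValueError(f"terminal {tree.symbol} out of range for {X.shape[1]} columns")
    return X[:, idx].astype(float)


def predict_chromosome(
    chrom: Chromosome, X: np.ndarray, fset: FunctionSet
) -> np.ndarray:
    """Linked prediction of all genes (NaN where any gene is invalid)."""
    trees = [decode_karva(g, fset) for g in chrom.genes]
    parts = [evaluate_tree(t, X, fset) for t in trees]
    out = parts[0]
    for p in parts[1:]:
        out = _apply(chrom.linking, [out, p])
    return out


def chromosome_infix(chrom: Chromosome, fset: FunctionSet) -> str:
    return chrom.linking.join(
        decode_karva(g, fset).infix() for g in chrom.genes
    )


def fitness_r2(chrom: Chromosome, X: np.ndarray, y: np.ndarray, fset: FunctionSet) -> float:
    """R² of the chromosome's prediction, floored at 0; invalid → 0."""
    pred = predict_chromosome(chrom, X, fset)
    if np.any(~np.isfinite(pred)):
        return 0.0
    y = np.asarray(y, float)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 0.0
    r2 = 1.0 - float(np.sum((y - pred) ** 2)) / ss_tot
    return max(0.0, r2)


# ---------------------------------------------------------------------------
# configuration and genetic operators
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GEPConfig:
    """Evolution parameters (canonical GEP defaults)."""

    population_size: int = 50
    max_generations: int = 200
    head_length: int = 8
    n_genes: int = 3
    linking: str = "+"
    mutation_rate: float = 0.044
    inversion_rate: float = 0.1
    is_rate: float = 0.1
    ris_rate: float = 0.1
    gene_transposition_rate: float = 0.1
    one_point_rate: float = 0.3
    two_point_rate: float = 0.3
    gene_recombination_rate: float = 0.1
    seed: int = 0
    fitness_target: float = 0.999999

    def __post_init__(self):
        rates = (
            self.mutation_rate,
            self.inversion_rate,
            self.is_rate,
            self.ris_rate,
            self.gene_transposition_rate,
            self.one_point_rate,
            self.two_point_rate,
            self.gene_recombination_rate,
        )
        if any(not 0 <= r <= 1 for r in rates):
            raise ValueError("operator rates must lie in [0, 1]")
        if self.population_size < 2:
            raise ValueError("population size must be ≥ 2")
        if self.head_length < 1 or self.n_genes < 1:
            raise ValueError("head length and gene count must be ≥ 1")


@dataclass(frozen=True)
class GEPResult:
    best_chromosome: Chromosome
    expression: str
    train_r2: float
    test_r2: Optional[float]
    train_mae: float
    test_mae: Optional[float]
    generation_found: int
    fitness_history: tuple[float, ...]

    def to_dict(self) -> dict:
        return {
            "expression": self.expression,
            "train_r2": self.train_r2,
            "test_r2": self.test_r2,
            "train_mae": self.train_mae,
            "test_mae": self.test_mae,
            "generation_found": self.generation_found,
        }


def _random_symbol(rng, fset: FunctionSet, head: bool) -> str:
    if head and rng.random() < 0.5:
        funcs = fset.function_symbols
        return funcs[rng.integers(len(funcs))]
    terms = fset.terminals
    return terms[rng.integers(len(terms))]


def random_gene(rng, fset: FunctionSet, head_length: int) -> Gene:
    t = head_length * (fset.max_arity - 1) + 1
    head = [_random_symbol(rng, fset, head=True) for _ in range(head_length)]
    tail = [_random_symbol(rng, fset, head=False) for _ in range(t)]
    return Gene(tuple(head + tail), head_length)


def random_chromosome(rng, fset: FunctionSet, config: GEPConfig) -> Chromosome:
    return Chromosome(
        tuple(random_gene(rng, fset, config.head_length) for _ in range(config.n_genes)),
        linking=config.linking,
    )


def mutate(chrom: Chromosome, rng, fset: FunctionSet, rate: float) -> Chromosome:
    """Point mutation: head positions draw any symbol, tail only terminals."""
    genes = []
    for g in chrom.genes:
        syms = list(g.symbols)
        for i in range(len(syms)):
            if rng.random() < rate:
                syms[i] = _random_symbol(rng, fset, head=i < g.head_length)
        genes.append(Gene(tuple(syms), g.head_length))
    return Chromosome(tuple(genes), chrom.linking)


def invert(chrom: Chromosome, rng, fset: FunctionSet) -> Chromosome:
    """Reverse a random stretch inside the head of one gene."""
    gi = int(rng.integers(len(chrom.genes)))
    g = chrom.genes[gi]
    h = g.head_length
    if h < 2:
        return chrom
    a, b = sorted(rng.choice(h, size=2, replace=False).tolist())
    syms = list(g.symbols)
    syms[a : b + 1] = syms[a : b + 1][::-1]
    genes = list(chrom.genes)
    genes[gi] = Gene(tuple(syms), h)
    return Chromosome(tuple(genes), chrom.linking)


def transpose_is(chrom: Chromosome, rng, fset: FunctionSet, max_len: int = 3) -> Chromosome:
    """Insertion-sequence transposition: copy a short fragment to a head
    position other than the root; the head is truncated to length."""
    gi = int(rng.integers(len(chrom.genes)))
    g = chrom.genes[gi]
    h = g.head_length
    if h < 2:
        return chrom
    length = int(rng.integers(1, max_len + 1))
    start = int(rng.integers(len(g.symbols) - length + 1))
    fragment = list(g.symbols[start : start + length])
    target = int(rng.integers(1, h))
    head = list(g.head)
    head = head[:target] + fragment + head[target:]
    head = head[:h]
    genes = list(chrom.genes)
    genes[gi] = Gene(tuple(head + list(g.tail)), h)
    return Chromosome(tuple(genes), chrom.linking)


def transpose_ris(chrom: Chromosome, rng, fset: FunctionSet, max_len: int = 3) -> Chromosome:
    """Root-insertion-sequence transposition: a fragment starting at a
    function symbol in the head is copied to the root."""
    gi = int(rng.integers(len(chrom.genes)))
    g = chrom.genes[gi]
    h = g.head_length
    func_positions = [i for i in range(h) if not fset.is_terminal(g.symbols[i])]
    if not func_positions:
        return chrom
    start = func_positions[int(rng.integers(len(func_positions)))]
    length = int(rng.integers(1, max_len + 1))
    fragment = list(g.symbols[start : start + length])
    head = (fragment + list(g.head))[:h]
    genes = list(chrom.genes)
    genes[gi] = Gene(tuple(head + list(g.tail)), h)
    return Chromosome(tuple(genes), chrom.linking)


def transpose_gene(chrom: Chromosome, rng) -> Chromosome:
    """Move a random gene to the front (identity for one-gene chromosomes)."""
    if len(chrom.genes) < 2:
        return chrom
    gi = int(rng.integers(1, len(chrom.genes)))
    genes = list(chrom.genes)
    g = genes.pop(gi)
    genes.insert(0, g)
    return Chromosome(tuple(genes), chrom.linking)


def _flat(chrom: Chromosome) -> list[str]:
    return [s for g in chrom.genes for s in g.symbols]


def _unflat(symbols: Sequence[str], template: Chromosome) -> Chromosome:
    genes = []
    pos = 0
    for g in template.genes:
        L = len(g.symbols)
        genes.append(Gene(tuple(symbols[pos : pos + L]), g.head_length))
        pos += L
    return Chromosome(tuple(genes), template.linking)


def recombine_one_point(a: Chromosome, b: Chromosome, rng) -> tuple[Chromosome, Chromosome]:
    fa, fb = _flat(a), _flat(b)
    cut = int(rng.integers(1, len(fa)))
    return _unflat(fa[:cut] + fb[cut:], a), _unflat(fb[:cut] + fa[cut:], b)


def recombine_two_point(a: Chromosome, b: Chromosome, rng) -> tuple[Chromosome, Chromosome]:
    fa, fb = _flat(a), _flat(b)
    i, j = sorted(rng.choice(len(fa), size=2, replace=False).tolist())
    ca = fa[:i] + fb[i:j] + fa[j:]
    cb = fb[:i] + fa[i:j] + fb[j:]
    return _unflat(ca, a), _unflat(cb, b)


def recombine_gene(a: Chromosome, b: Chromosome, rng) -> tuple[Chromosome, Chromosome]:
    gi = int(rng.integers(len(a.genes)))
    ga, gb = list(a.genes), list(b.genes)
    ga[gi], gb[gi] = gb[gi], ga[gi]
    return Chromosome(tuple(ga), a.linking), Chromosome(tuple(gb), b.linking)


# ---------------------------------------------------------------------------
# evolution loop
# ---------------------------------------------------------------------------


def _roulette(rng, fitness: np.ndarray) -> int:
    total = float(fitness.sum())
    if total <= 0:
        return int(rng.integers(len(fitness)))
    return int(rng.choice(len(fitness), p=fitness / total))


def evolve(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray | None = None,
    y_test: np.ndarray | None = None,
    config: GEPConfig = GEPConfig(),
    fset: FunctionSet | None = None,
) -> GEPResult:
    """Run the GEP evolution loop; fully determined by ``config.seed``.

    Generational replacement with single-elite cloning (best-so-far fitness
    is non-decreasing); stops early when fitness reaches
    ``config.fitness_target``.
    """
    X_train = np.atleast_2d(np.asarray(X_train, float))
    y_train = np.asarray(y_train, float)
    if len(y_train) < 5:
        raise ValueError("need at least 5 training rows")
    if fset is None:
        fset = FunctionSet(n_terminals=X_train.shape[1])

    rng = np.random.default_rng(config.seed)

    # initial population; redraw a bounded number of times if everything is invalid
    for attempt in range(20):
        population = [random_chromosome(rng, fset, config) for _ in range(config.population_size)]
        fitness = np.array([fitness_r2(c, X_train, y_train, fset) for c in population])
        if fitness.max() > 0:
            break
    else:
        raise RuntimeError(
            "could not seed a population with any valid chromosome; "
            "try a smaller head length"
        )

    best_idx = int(fitness.argmax())
    best = population[best_idx]
    best_fitness = float(fitness[best_idx])
    generation_found = 0
    history = [best_fitness]

    for gen in range(1, config.max_generations + 1):
        if best_fitness >= config.fitness_target:
            break
        new_pop = [best]  # elite clone
        while len(new_pop) < config.population_size:
            a = population[_roulette(rng, fitness)]
            if (
                rng.random() < config.one_point_rate + config.two_point_rate + config.gene_recombination_rate
            ):
                b = population[_roulette(rng, fitness)]
                u = rng.random() * (
                    config.one_point_rate + config.two_point_rate + config.gene_recombination_rate
                )
                if u < config.one_point_rate:
                    a, b2 = recombine_one_point(a, b, rng)
                elif u < config.one_point_rate + config.two_point_rate:
                    a, b2 = recombine_two_point(a, b, rng)
                else:
                    a, b2 = recombine_gene(a, b, rng)
            a = mutate(a, rng, fset, config.mutation_rate)
            if rng.random() < config.inversion_rate:
                a = invert(a, rng, fset)
            if rng.random() < config.is_rate:
                a = transpose_is(a, rng, fset)
            if rng.random() < config.ris_rate:
                a = transpose_ris(a, rng, fset)
            if rng.random() < config.gene_transposition_rate:
                a = transpose_gene(a, rng)
            new_pop.append(a)
        population = new_pop
        fitness = np.array([fitness_r2(c, X_train, y_train, fset) for c in population])
        gen_best = int(fitness.argmax())
        if float(fitness[gen_best]) > best_fitness:
            best_fitness = float(fitness[gen_best])
            best = population[gen_best]
            generation_found = gen
        history.append(best_fitness)

    pred_train = predict_chromosome(best, X_train, fset)
    train_mae = _mae(y_train, pred_train) if np.all(np.isfinite(pred_train)) else math.inf
    test_r2 = test_mae = None
    if X_test is not None and y_test is not None and len(np.asarray(y_test)) > 0:
        X_test = np.atleast_2d(np.asarray(X_test, float))
        y_test = np.asarray(y_test, float)
        pred_test = predict_chromosome(best, X_test, fset)
        if np.all(np.isfinite(pred_test)):
            ss_tot = float(np.sum((y_test - y_test.mean()) ** 2))
            test_r2 = 1.0 - float(np.sum((y_test - pred_test) ** 2)) / ss_tot if ss_tot > 0 else None
            test_mae = _mae(y_test, pred_test)

    return GEPResult(
        best_chromosome=best,
        expression=chromosome_infix(best, fset),
        train_r2=best_fitness,
        test_r2=test_r2,
        train_mae=train_mae,
        test_mae=test_mae,
        generation_found=generation_found,
        fitness_history=tuple(history),
    )
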