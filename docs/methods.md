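# Methods

This note documents the inference semantics, the numerical/algorithmic
choices made where the design was genuinely open, what the synthetic test
surface does and does not cover, and the known limitations.

## Inputs

**Guideline model.** A restricted BPMN 2.0 process: exactly one plain start
event, end events, tasks (all BPMN task subtypes are collapsed — the model
only distinguishes "activities"), exclusive and parallel gateways, and
sequence flows with optional condition expressions.  Mixed gateways
(simultaneous split + join) are rejected: the supported workflow control
patterns never need them and excluding them keeps join semantics
unambiguous.  A gateway that neither splits nor joins is likewise rejected.
Vertices on no path from the start are reported as warnings and pruned from
every contextualization.  The document order of every element is recorded
and serves as the single deterministic tie-breaker throughout the pipeline.

**Treatment context.** `executed` maps task ids to recorded scalar outcomes
(boolean, number or string); `variables` maps names to scalars.  Executed
outcomes are exposed to conditions under the task id unless shadowed by an
explicit variable.  A name absent from the context is *unknown*, not false.

**Condition language.** Comparisons (`==`, `!=`, `<`, `<=`, `>`, `>=`),
boolean connectives (`not`, `and`, `or`), parentheses, boolean/number/string
literals and variable references.  This replaces the Java Unified
Expression Language of typical BPMN engines with the smallest portable
language sufficient for guideline guards; it is parsed by a hand-written
recursive-descent parser with position-reporting errors.  Two deliberate
typing rules:

* an *absent* variable makes the enclosing comparison `UNKNOWN` — missing
  data is a normal state, never an error;
* a type mismatch between *present* values (ordering on strings, equality
  across kinds, a number in boolean position) raises an error — it signals
  a broken model/context contract, which silent `UNKNOWN` would hide.

## Inference

### Three-valued reachability (pruning)

Edge guards evaluate to `TRUE`, `FALSE` or `UNKNOWN` under Kleene's strong
three-valued logic.  Reachability is the least fixpoint of

* `reach(start) = TRUE`,
* `avail(u→v) = AND3(reach(u), cond(u→v))`,
* `reach(v)` = Kleene conjunction of incoming `avail` at a parallel join,
  Kleene disjunction elsewhere,

iterated from all-`FALSE`.  Because `AND3`/`OR3` are monotone in the
information order `FALSE ≤ UNKNOWN ≤ TRUE`, values only ever move upward
and the iteration terminates after at most |V|·|E| updates.  `reach(v) =
FALSE` means *v* is unreachable under every completion of the unknown data;
exactly those vertices are pruned.  Edges whose effective guard is `FALSE`
are also dropped from the surviving subgraph even when both endpoints
survive.

### Exclusive-split resolution

BPMN leaves the interplay of multiple true/undecided XOR branch conditions
open.  We commit to the deterministic reading "the first (document order)
satisfied condition wins; the unconditioned default fires when every
condition fails", translated exactly into Kleene logic:

```
chosen(e_i)   = cond(e_i) ∧ ¬cond(e_1) ∧ … ∧ ¬cond(e_{i-1})
chosen(default) = ¬cond(e_1) ∧ … ∧ ¬cond(e_n)
```

Consequences: a decidedly-true branch forces every *later* branch false,
but remains `UNKNOWN` while an *earlier*-priority branch is still
undecided — the pending data could hand the choice to the earlier branch.
This is precisely the limit of the two-valued first-true-wins semantics
over all completions of the unknowns, which is what makes the engine agree
with the brute-force oracle below.  With no default and all conditions
false, no branch fires and everything downstream prunes.

### Confirmed-facts arrival (what is enabled now)

A separate two-valued token game decides where control has definitely
arrived: an edge delivers only when its effective guard is decidedly
`TRUE` and its source has delivered — a task delivers iff it was actually
*executed* (recorded history is trusted, even for tasks no enabled path
reaches; such off-pathway records produce a warning, because real
treatment contexts may legitimately contain them and a stateless engine
cannot reject history), while events and gateways deliver once arrived at.
A parallel join requires all incoming edges to deliver, everything else
any.

### Temporal roles

For each surviving task:

* **past** — executed and unable to recur: it lies on no directed cycle of
  the surviving subgraph.  A task executed with outcome `false` is still
  `past`: falseness gates downstream guards, not the fact of execution.
* **present** — arrived and not yet executed, or executed but re-enabled
  (arrived again) on a live cycle; "a choice that can currently be taken"
  takes precedence over `future` for re-executable tasks.
* **future** — everything else that survives pruning.

Events and gateways receive internal roles by the same arrival rules
(never `past`) but are structural: they are excluded from the user-facing
task list.

### Linearization

1. **BFS distances** from the start vertex over the pruned graph (edge
   counts).
2. **Cycle breaking**: while a cycle remains, remove — among all edges
   lying on any cycle — the one maximizing `(dist(source), dist(target),
   document order)`; i.e. the edge of each circle farthest from the start.
   Selecting over all cyclic edges at once makes the result independent of
   cycle-discovery order.  The removed edge `(u, v)` always satisfies
   `dist(v) ≤ dist(u)` (if `dist(v)` exceeded every cycle-edge source
   distance it could not itself be a cycle-edge source, which it is), so a
   path through it costs at least `dist(u) + 1 > dist(v)`: no shortest path
   uses the removed edge, hence every vertex stays start-reachable and the
   precomputed distances remain valid without recomputation.  Whether
   "farthest" means source or target distance was an open choice; source
   distance, breaking ties by target distance and then by *later* document
   order (the "last" edge of the circle), is the committed one.
3. **Modified Kahn sort**: among ready (in-degree-zero) vertices prefer a
   direct successor of the most recently emitted vertex, then the smallest
   BFS distance, then the smallest document order.  The successor
   preference keeps parallel branches contiguous instead of interleaved;
   the remaining keys make the order total and deterministic.

## The synthetic test surface

**Pattern fixtures.**  Six canonical workflow control patterns are
generated in code: sequence, parallel split, synchronization, exclusive
choice, simple merge, structured loop.  The synchronization fixture (AND
split to tasks A and B, AND join guarded by `A == true` / `B == true`,
then task C) carries its nine exhaustive two-task contexts with fixed
expected roles; the other fixtures carry exhaustive
{executed-true, executed-false, absent} grids (capped at 3^6 contexts)
whose expectations come from the independent oracle.

**Random structured models.**  Block-nested composition of
sequence/XOR/AND/loop blocks around a task budget, with every condition
referencing a fresh variable (`V1 == true`, …), so conditions are pairwise
independent by construction.  Defaults: `p_xor = 0.25`, `p_and = 0.2`,
`p_loop = 0.15` — enough decision, concurrency and repetition structure to
exercise every inference rule while keeping models the size of realistic
guideline fragments.  A loop's immediate body is never itself a loop,
bounding the number of loop conditions by the task budget.  Random
contexts assign each task executed-true/false/unexecuted uniformly and
each condition variable true/false/absent with probabilities
0.35/0.35/0.30, leaving at most 12 variables unknown so that the
completion oracle below stays tractable (2^12 completions worst case).

**Brute-force oracle.**  Reachability ground truth is obtained by
enumerating every boolean completion of the absent variables referenced by
conditions (refusing above a cap, default 16): a vertex is pruned iff
unreachable under *all* completions; a task can recur iff some completion
contains a cycle of satisfied edges reachable in that same completion.
Arrival and the role rules are recomputed with independent traversal code
(plain fixpoints and a hand-rolled Kosaraju SCC, no shared graph
machinery).  Enumerating *variables* rather than individual conditions
means the oracle performs cross-condition reasoning the engine does not
(see Limitations).

**What passing does and does not show.**  The fixtures cover the gateway
semantics, guard logic, recurrence and ordering rules exhaustively at
small scale, and the randomized suite covers their composition.  They do
not emulate real guideline content: conditions are mostly boolean
one-variable guards, contexts are synthetic, and clinical phenomena such
as time stamps, repeated executions with histories, or semantically
correlated criteria are absent.  Agreement with the oracle validates the
control-flow semantics, not medical adequacy.

## Design decisions on open points

* Multiple simultaneously satisfiable XOR conditions: resolved by document
  order (first wins).  An error or explicit priorities would also be
  defensible; document order is the common BPMN modeling convention and
  preserves determinism.
* Gateway/event roles are computed but never surfaced in the task list;
  the linearized view is a task list by design.
* The medical-criteria layer is a pluggable resolver
  (`criterion id × context → TRUE/FALSE/UNKNOWN`); the default resolver
  treats the id as a condition expression.  Resolver exceptions degrade to
  `UNKNOWN` with a warning: a failing knowledge module must not crash a
  stateless re-run.
* The patient-data wire format is a minimal JSON schema (see
  `src/cigpath/schemas/`); richer clinical models (e.g. FHIR) are out of
  scope.

## Known limitations

* **Local condition evaluation.**  Kleene evaluation is per-edge: several
  guards over the same unknown variable are not reasoned about jointly, so
  a path requiring `X == true` and later `X == false` is kept as `future`
  although no value of `X` realizes it (the oracle prunes it).  This is
  sound — the engine never prunes anything reachable — and linear-time;
  the engine/oracle equivalence suites therefore restrict to
  distinct-variable models, and the divergence is pinned by a dedicated
  test.
* **Consistency of histories.**  Execution records are trusted verbatim.
  For histories inconsistent with the flow (a task recorded as executed
  that no enabled path reaches) the engine warns but proceeds; the
  "PAST\* PRESENT? FUTURE\*" shape of linearized chains is guaranteed only
  for flow-consistent histories.
* **Expressiveness.**  No OR-gateways, sub-processes, boundary/timer
  events, multi-instance or cancellation patterns; no arithmetic or
  temporal operators inside conditions; string comparison is equality
  only.
* **Problem sizes.**  The validation suites use 1000 random models of up
  to 12 tasks with exhaustive or randomized contexts — sizes at which the
  completion-enumeration oracle is exact; behaviour on much larger models
  is covered by the algorithmic termination/determinism arguments, not by
  oracle comparison.
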