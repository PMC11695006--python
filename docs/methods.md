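# Methods

## The specification model

A model workbook defines four families of named quantities: state variables
(differential definitions with initial conditions), algebraic variables
(closed-form definitions), free parameters (reference values, overridable
per configuration) and determined parameters (computed from other
parameters). Names are matched case-sensitively — the target dialects are
case-sensitive, and silent case-folding would corrupt generated code. The
identifier `t` is reserved for simulation time.

Determined parameters may depend on free and other determined parameters
only, never on states or time: they are resolved once, before integration,
in topological order of the dependency graph, so declaration order never
matters. Initial conditions are accepted as expressions of parameters (and
the start time), a superset of literal values; they may not reference
variables, whose values do not exist before integration starts. Constraints
are predicates over parameters only. The subgraph spanned by determined
parameters and algebraic variables must be acyclic; a state variable
referencing itself in its own derivative is, of course, the normal case and
never flagged.

A configuration named `Default` (reference values, no overrides) is
synthesized automatically when a workbook does not declare one, so every
model always has a default scenario.

## The pseudocode language

The grammar is fixed as C-style infix arithmetic: `^` for power
(right-associative), unary minus binding between `^` and `*`/`/`, the six
comparisons (`=` is accepted as an alias of `==`), keyword logicals
`and`/`or`/`not`, named builtins with parentheses, and `If(cond, then,
else)` evaluating only the taken branch. Comparison chaining (`a < b < c`)
is a syntax error because its meaning differs across the target dialects.
Truth values are 1/0 so logical results compose with arithmetic
identically in every dialect. The conditional and the logicals are
extensions of this implementation and are flagged as such in the
template's Instructions sheet.

Shipped builtins: `RandUnif()` (uniform on [0,1)), `Exp`, `Ln`, `Sqrt`,
`Abs`, `Min`, `Max`, `Pow`, `Step` (Heaviside with `Step(0) = 1`), `Sin`,
`Cos`. Unknown function names are validation errors, never pass-through
text: silent pass-through would break the multi-dialect guarantee. The
registry is an extension point — adding a builtin means providing its
arity, numeric semantics and a spelling per dialect table.

## Integration

The single scheme is the classical four-stage fixed-step fourth-order
Runge–Kutta tableau (stages at `t`, `t+h/2`, `t+h/2`, `t+h`). Algebraic
variables are re-evaluated at **every stage point**, not frozen per step;
freezing them would degrade mixed algebraic/differential systems below
fourth order. The observed convergence order on an exponential-decay
problem rounds to 4 (step-halving test).

The time grid is `{t_start + k·h}` with the final point always exactly
`t_end`, via a shortened last step when the span is not a step multiple;
a relative tolerance of `1e-9·h` decides whether the last regular point
*is* `t_end` (floating-point grids rarely land exactly). The grid lives in
the GeneralControls sheet (`TStart`/`TEnd`/`TStep`) with CLI overrides.

Constraints are checked once, pre-integration, on the resolved parameter
environment; a violation refuses to integrate and carries the declared
error codes in declaration order. Variable range fields (min/max on the
Variables sheet) are soft: excursions become warnings on the result, never
failures. If the state goes non-finite the trajectory is truncated at the
last finite point and flagged, so partial runs remain inspectable and
plottable rather than lost to an exception.

`RandUnif` draws from a generator seeded per simulation, so identical
(spec, configuration, grid, seed) inputs are bit-reproducible. Stochastic
expressions are **not** promised to agree across dialects: each generated
package uses its language's native uniform stream. The bundled fixtures are
deterministic, which is what makes the cross-implementation agreement
checks meaningful.

## Code generation and the twins property

Each emitted package contains the same routines under the same names —
`ModelPars`, `ModelRHS`, `AlgebraicValues`, `InitialConditions`,
`RK4Step`/`TimeGrid`/`Integrate`, `CheckConstraints` — plus the
`<Project>AutoTester` entry script. The generated integrator is the same
RK4 written out in each dialect rather than a call into a native solver
library: cross-dialect numerical agreement matters more than reusing
`deSolve` or `DifferentialEquations.jl`, and one scheme is the contract.

The renderer parenthesizes emitted expressions so that the generated code
performs the same floating-point operations in the same order as the
in-process evaluator, and the emitted grid/stage arithmetic mirrors the
in-process formulas token for token. The result is that the host-dialect
package (and, in practice, the R package too) reproduces in-process
trajectories bit-for-bit; the acceptance checks require ≤ 1e-12 per value.
Headers carry the workbook version string and no timestamps, so
regeneration from an unchanged spec is byte-identical — non-host emissions
are therefore verifiable as frozen golden text, and the R emission is
additionally executed and compared in the test suite.

Workbook text placed into generated comments is flattened to one line with
quotes and backslashes neutralised, so descriptive cells cannot inject
code. One known sharp edge: generated R functions bind parameters as local
variables, so a parameter named after an R builtin shadows it; the emitter
namespaces its own base calls (`base::c`) to stay immune, but a model that
names a parameter `exp` and also calls `Exp(...)` in the same definition
would collide in R. The two structural files
(`<Project>.modpars.dat`, `<Project>.vars.dat`) use a headered
tab-separated layout — structural, diff-friendly, trivially parseable from
any of the dialects.

## The Companion document

Mathematical notation is synthesized from the AST with a fixed mapping
(division → `\frac`, power → superscript, `Exp` → `e^{...}`, `Step` → `H(·)`,
builtins → operator names), chosen for determinism over typographic beauty:
regeneration is byte-identical, and every equation block's verbatim half is
string-equal to the code generator's rendering of the same AST — the
document exists so a modeler can check that the generated code says exactly
what the intended equation says. Description text is escaped against the
LaTeX special set; `latex_name`/`latex_text` cells are trusted raw LaTeX,
since carrying LaTeX is their purpose. The `Tab length`/`Name length`
controls are passed through verbatim as column widths. Compiling the
emitted sources needs a LaTeX toolchain and is not attempted by the test
suite; the string-level contracts are the verification surface.

## Workbooks

Both `.ods` and `.xlsx` containers are read and written. Sheet lookup keys
on the leading integer prefix (`2-Variables`, `2-Variable` — naming in the
wild is inconsistent), columns are keyed by header name rather than
position, trailing blank rows and extra "support" sheets are ignored, and
numbers are accepted from numeric cells or plain decimal-literal text —
anything else in a numeric column is a named error (sheet, row, column),
never a silent zero. Locale quirks are rejected: decimal points only, no
thousands separators. Cell colour (yellow fill-in cells, purple
determined-parameter rows) is write-only decoration; the free/determined
distinction travels in an explicit Kind column because colours are
invisible to many toolchains and must never carry semantics. Blank optional
cells map to explicit absent values (`None`), not empty strings. The `.ods`
backend is a minimal reader/writer for the slice of OpenDocument the format
needs (typed float/string cells, repeated-cell expansion, background
styles).

## Fixtures: what they emulate and what they do not

`TwoLovers` is a linear 2×2 system chosen so that closed forms exist: its
`Decoupled` configuration reduces to pure exponential decay (terminal value
`e^(−1)`, checked to 1e-8) and any configuration is checkable against the
matrix exponential (1e-6 at step 0.01, with a series-based exponential as
the independent oracle in the acceptance script). `SEIR` has derivatives
summing identically to zero, so total population is conserved — a
structural property the integrator must preserve to relative 1e-9 — plus a
determined reproduction-number parameter and a positivity constraint (error
code 201). `ConstrainedToy` exercises time-dependent forcing (`Step(t-1)`),
algebraic clipping (`Min`), two constraints (codes 101/102) with
deliberately violating configurations, figures and datasets.

These are small, smooth, non-stiff systems with a handful of parameters.
Passing tests therefore demonstrate the machinery — parsing, validation,
ordering, integration accuracy at fourth order, cross-dialect agreement,
round-trip fidelity — not performance or robustness on stiff, large or
noisy real-world models: there is no adaptive step control, no stiffness
handling, no event detection, and the expression-tree evaluator prioritises
correctness and cross-path identity over speed. Problem sizes used by the
default checks: grids of 101–3201 points, 1,000 random expressions × 10
evaluation points, all digraphs on ≤ 4 nodes exhaustively (65,536 at n=4)
with seeded samples at 5–6 nodes — the space of 6-node digraphs (2^36) is
not exhaustively enumerable, so "exhaustive" is bounded at 4.

## Other design choices at genuinely open points

- The plotting surface has eight compass quadrants (NW, N, NE, W, E, SW, S,
  SE) and at most four overlaid configurations in the fixed colour order
  black/blue/green/red; display-variable lists are capped at the quadrant
  count.
- The interactive parameter-slider workflow is replaced by a
  `--scan parameter=lo:hi:n` sweep producing an overlay plot.
- Emission dialects are python (host), r and julia; the C++ and Matlab
  special-code sheets are read, stored and round-tripped so workbooks stay
  complete, but no package emitter exists for them.
- Julia output is verified as golden text only; no Julia runtime is assumed
  by the test suite, while the R output is executed and compared.
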