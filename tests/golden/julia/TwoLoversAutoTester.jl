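# TwoLoversAutoTester.jl - entry point
# Generated by the mospec Autocoder from TwoLovers.MoSpec V02.04.03
# Do not edit: regenerate from the model workbook instead.

using Printf

include("TwoLoversModelPars.jl")
include("TwoLoversModelRHS.jl")
include("TwoLoversConstraintCheck.jl")
include("RK4Solver.jl")

const T_START = 0.0
const T_END = 20.0
const T_STEP = 0.01

pars = ModelPars("Default")
violated = CheckConstraints(pars)
if !isempty(violated)
    println("constraint violation; error codes: ", violated)
    exit(3)
end
times = TimeGrid(T_START, T_END, T_STEP)
y0 = InitialConditions(pars, times[1])
states = Integrate((tt, yy) -> ModelRHS(tt, yy, pars), times, y0)
open("TwoLovers_trajectory.csv", "w") do fh
    println(fh, "time,R,J,TotalAffection")
    for i in eachindex(times)
        alg = AlgebraicValues(times[i], states[i, :], pars)
        row = vcat(times[i], states[i, :], alg)
        println(fh, join([@sprintf("%.17g", v) for v in row], ","))
    end
end
println("wrote TwoLovers_trajectory.csv (", length(times), " points)")
# plotting requires the Plots package; skipped when unavailable
try
    @eval using Plots
    plt = plot(times, states, label = permutedims(STATE_NAMES), xlabel = "time")
    savefig(plt, "TwoLovers_plot.png")
    println("wrote TwoLovers_plot.png")
catch err
    println("plotting skipped: ", err)
end

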