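# TwoLoversModelRHS.jl - model right-hand side
# Generated by the mospec Autocoder from TwoLovers.MoSpec V02.04.03
# Do not edit: regenerate from the model workbook instead.

const STATE_NAMES = ["R", "J"]
const ALGEBRAIC_NAMES = ["TotalAffection"]

function AlgebraicValues(t, y, pars)
    a = pars["a"]
    b = pars["b"]
    c = pars["c"]
    d = pars["d"]
    R0 = pars["R0"]
    J0 = pars["J0"]
    CouplingGain = pars["CouplingGain"]
    R = y[1]
    J = y[2]
    TotalAffection = R + J
    Float64[TotalAffection]
end

function ModelRHS(t, y, pars)
    a = pars["a"]
    b = pars["b"]
    c = pars["c"]
    d = pars["d"]
    R0 = pars["R0"]
    J0 = pars["J0"]
    CouplingGain = pars["CouplingGain"]
    R = y[1]
    J = y[2]
    TotalAffection = R + J
    d_R = a * R + b * J
    d_J = c * R + d * J
    Float64[d_R, d_J]
end

function InitialConditions(pars, t)
    a = pars["a"]
    b = pars["b"]
    c = pars["c"]
    d = pars["d"]
    R0 = pars["R0"]
    J0 = pars["J0"]
    CouplingGain = pars["CouplingGain"]
    Float64[R0, J0]
end

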