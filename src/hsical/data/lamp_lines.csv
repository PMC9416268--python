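species,wavelength_air_nm,relative_intensity
H,410.174,15
H,434.047,30
H,486.135,80
H,656.279,120
Hg/Ar,404.656,65
Hg/Ar,435.833,100
Hg/Ar,546.074,90
Hg/Ar,579.066,32
Hg/Ar,696.543,40
Hg/Ar,706.722,30
Hg/Ar,727.294,10
Hg/Ar,738.398,20
Hg/Ar,750.387,45
Hg/Ar,763.511,60
Hg/Ar,772.376,25
Hg/Ar,794.818,20
Hg/Ar,800.616,25
Hg/Ar,811.531,70
Hg/Ar,826.452,30
Hg/Ar,842.465,35
Hg/Ar,852.144,15
Hg/Ar,866.794,10
Hg/Ar,912.297,50
Hg/Ar,922.450,20
Hg/Ar,965.779,15
He,388.865,50
He,402.619,5
He,447.148,90
He,471.314,15
He,492.193,20
He,501.568,60
He,587.562,100
He,667.815,50
He,706.519,30
He,728.135,12
Ne,540.056,25
Ne,585.249,100
Ne,594.483,25
Ne,603.000,15
Ne,609.616,40
Ne,614.306,60
Ne,621.728,25
Ne,626.650,40
Ne,633.443,45
Ne,640.225,90
Ne,650.653,70
Ne,659.895,35
Ne,667.828,50
Ne,692.947,40
Ne,703.241,65
Ne,717.394,25
Ne,724.517,45
Ne,743.890,30
Ne,748.887,20
Ne,753.577,25
Ne,794.318,20
Ne,813.641,15
Ne,830.033,20
Ne,837.761,30
Ne,849.536,25
Ne,865.438,25
Ne,878.062,20
Ne,885.387,15
Ne,891.950,12
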