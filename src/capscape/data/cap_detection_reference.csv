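label,detect_20_50,detect_50_100,detect_gt100,calculated_mass,observed_mass,error_ppm
3mGpppAm/Amppp3mG,detected,detected,detected,827.1294,827.1308,1.69
3mGpppmAm/mAmppp3mG,ND,ND,detected,841.1450,841.1466,1.90
2mGpppAm(1)/Amppp2mG(1),ND,ND,detected,813.1138,813.1157,2.34
2mGpppAm(2)/Amppp2mG(2),ND,ND,detected,813.1138,813.1157,2.34
mGpppmAm/mAmpppmG,detected,ND,detected,813.1138,813.1157,2.34
3mGpppA/Appp3mG,ND,ND,detected,813.1138,813.1157,2.34
3mGpppCm/Cmppp3mG,ND,ND,detected,803.1184,803.1198,1.74
3mGpppGm/Gmppp3mG,ND,ND,detected,843.1244,843.1261,2.02
3mGpppUm/Umppp3mG,ND,ND,detected,804.1024,804.1041,2.11
mGpppGm/GmpppmG,detected,ND,detected,815.0932,815.0951,2.33
mGpppAm/AmpppmG,ND,ND,detected,799.0982,799.1005,2.88
mGpppCm/CmpppmG,detected,ND,detected,775.0872,775.0885,1.68
mGpppUm/UmpppmG,detected,ND,ND,776.0712,776.0725,1.68
mGpppG/GpppmG,detected,ND,ND,801.078,801.079,1.25
mGpppA/ApppmG,detected,ND,ND,785.083,785.0836,0.76
GpppCm/CmpppG,detected,ND,ND,761.0716,761.073,1.84
GpppGm/GmpppG,detected,ND,ND,801.078,801.0791,1.37
GpppG,detected,ND,detected,787.062,787.0632,1.52
GpppA/ApppG,detected,ND,detected,771.067,771.069,2.59
GpppmAm/mAmpppG,detected,ND,detected,799.0982,799.1006,3.00
Y1pppAm/AmpppY1,ND,ND,detected,,841.1104,
2mGpppY2/Y2ppp2mG,ND,ND,detected,,825.1156,
Y3pppAm/AmpppY3,ND,ND,detected,,846.1272,
Y4pppAm/AmpppY4,ND,ND,detected,,774.1057,
Y5pppAm/AmpppY5,ND,ND,detected,,748.127,
Y6pppAm/AmpppY6,ND,ND,detected,,875.154,
Y7pppAm/AmpppY7,ND,ND,detected,,875.154,
Y8pppAm/AmpppY8,ND,ND,detected,,845.143,
Y9pppAm/AmpppY9,ND,ND,detected,,843.1267,
Y10pppAm/AmpppY10,ND,ND,detected,,843.1253,
Y11pppAm/AmpppY11,ND,ND,detected,,760.0894,
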