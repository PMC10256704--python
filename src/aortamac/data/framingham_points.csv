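# framingham_points schema_version: 1
# Sex-specific general cardiovascular disease risk points (office-based BMI
# variant used when lipids are unavailable). Numeric bands are [lower, upper);
# blank lower/upper mean -inf/+inf, so out-of-range inputs fall in the
# terminal band. treated applies to sbp rows only (1 = on BP medication).
variant,sex,component,lower,upper,category,treated,points
both,female,age,,35,,,0
both,female,age,35,40,,,2
both,female,age,40,45,,,4
both,female,age,45,50,,,5
both,female,age,50,55,,,7
both,female,age,55,60,,,8
both,female,age,60,65,,,9
both,female,age,65,70,,,10
both,female,age,70,75,,,11
both,female,age,75,,,,12
both,male,age,,35,,,0
both,male,age,35,40,,,2
both,male,age,40,45,,,5
both,male,age,45,50,,,6
both,male,age,50,55,,,8
both,male,age,55,60,,,10
both,male,age,60,65,,,11
both,male,age,65,70,,,12
both,male,age,70,75,,,14
both,male,age,75,,,,15
lipid,female,total_chol,,160,,,0
lipid,female,total_chol,160,200,,,1
lipid,female,total_chol,200,240,,,3
lipid,female,total_chol,240,280,,,4
lipid,female,total_chol,280,,,,5
lipid,male,total_chol,,160,,,0
lipid,male,total_chol,160,200,,,1
lipid,male,total_chol,200,240,,,2
lipid,male,total_chol,240,280,,,3
lipid,male,total_chol,280,,,,4
lipid,female,hdl,,35,,,2
lipid,female,hdl,35,45,,,1
lipid,female,hdl,45,50,,,0
lipid,female,hdl,50,60,,,-1
lipid,female,hdl,60,,,,-2
lipid,male,hdl,,35,,,2
lipid,male,hdl,35,45,,,1
lipid,male,hdl,45,50,,,0
lipid,male,hdl,50,60,,,-1
lipid,male,hdl,60,,,,-2
bmi,female,bmi,,25,,,0
bmi,female,bmi,25,30,,,1
bmi,female,bmi,30,,,,2
bmi,male,bmi,,25,,,0
bmi,male,bmi,25,30,,,1
bmi,male,bmi,30,,,,2
both,female,sbp,,120,,0,-3
both,female,sbp,120,130,,0,0
both,female,sbp,130,140,,0,1
both,female,sbp,140,150,,0,2
both,female,sbp,150,160,,0,4
both,female,sbp,160,,,0,5
both,female,sbp,,120,,1,-1
both,female,sbp,120,130,,1,2
both,female,sbp,130,140,,1,3
both,female,sbp,140,150,,1,5
both,female,sbp,150,160,,1,6
both,female,sbp,160,,,1,7
both,male,sbp,,120,,0,-2
both,male,sbp,120,130,,0,0
both,male,sbp,130,140,,0,1
both,male,sbp,140,160,,0,2
both,male,sbp,160,,,0,3
both,male,sbp,,120,,1,0
both,male,sbp,120,130,,1,2
both,male,sbp,130,140,,1,3
both,male,sbp,140,160,,1,4
both,male,sbp,160,,,1,5
both,female,smoking,,,current,,3
both,male,smoking,,,current,,4
both,female,diabetes,,,yes,,4
both,male,diabetes,,,yes,,3
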