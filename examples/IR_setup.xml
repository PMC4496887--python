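<?xml version='1.0' encoding='utf-8'?>
<simulation-setup mode="ssa" seed="42" replicates="1">
  <end t-end="172800.0" />
  <volume liters="1e-09" />
  <avogadro value="6e+23" />
  <places>
    <place name="IR" concentration="9e-13" />
    <place name="IR_I" concentration="0.0" />
    <place name="IR_I_P" concentration="0.0" />
    <place name="IR_I_P_Int" concentration="0.0" />
    <place name="IR_Int" concentration="1e-13" />
    <place name="Insulin" expression="(Time % 86400.0) &gt;= 32400.0 ; (Time % 86400.0) &lt; 43200.0 : 36000.0 + 180000.0 * exp(-((Time % 86400.0) - 32400.0) / 2345.19020227756) ; (Time % 86400.0) &gt;= 46800.0 ; (Time % 86400.0) &lt; 57600.0 : 36000.0 + 180000.0 * exp(-((Time % 86400.0) - 46800.0) / 2345.19020227756) ; (Time % 86400.0) &gt;= 64800.0 ; (Time % 86400.0) &lt; 75600.0 : 36000.0 + 180000.0 * exp(-((Time % 86400.0) - 64800.0) / 2345.19020227756) ; 36000.0" />
  </places>
  <rates>
    <rate transition="Bind_Insulin" kind="mass_action" value="1000000.0" />
    <rate transition="Diss_Insulin" kind="mass_action" value="0.00333" />
    <rate transition="Inter_IR" kind="mass_action" value="5.56e-06" />
    <rate transition="Phos_IR_I" kind="mass_action" value="41.66" />
    <rate transition="Dephos_IR_I_P" kind="mass_action" value="0.00333" />
    <rate transition="Inter_IR_I_P" kind="mass_action" value="3.5e-05" />
    <rate transition="Deinter_IR_I_P" kind="mass_action" value="3.5e-06" />
    <rate transition="Dephos_IR_I_P_Int" kind="mass_action" value="0.00768" />
    <rate transition="Deinter_IR" kind="mass_action" value="5e-05" />
    <rate transition="Degradation" kind="mass_action" value="2.783e-06" />
    <rate transition="Synthesis" kind="conditional" expression="IR_Int + IR_I_P_Int &gt;= 60 : 2.78e-19 ; 1.67e-18" />
  </rates>
  <leap critical-threshold="20" epsilon="0.03" max-halvings="10" />
  <sync fraction="1.0" />
  <record interval="60.0" />
</simulation-setup>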