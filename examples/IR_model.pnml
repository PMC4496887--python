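<?xml version='1.0' encoding='utf-8'?>
<pnml xmlns="http://www.pnml.org/version-2009/grammar/pnml">
  <net id="net0" type="http://www.pnml.org/version-2009/grammar/ptnet">
    <page id="page0">
      <place id="Insulin">
        <name>
          <text>Insulin</text>
        </name>
        <toolspecific tool="stochpn" version="1">
          <constant>true</constant>
          <expression>(Time % 86400.0) &gt;= 32400.0 ; (Time % 86400.0) &lt; 43200.0 : 36000.0 + 180000.0 * exp(-((Time % 86400.0) - 32400.0) / 2345.19020227756) ; (Time % 86400.0) &gt;= 46800.0 ; (Time % 86400.0) &lt; 57600.0 : 36000.0 + 180000.0 * exp(-((Time % 86400.0) - 46800.0) / 2345.19020227756) ; (Time % 86400.0) &gt;= 64800.0 ; (Time % 86400.0) &lt; 75600.0 : 36000.0 + 180000.0 * exp(-((Time % 86400.0) - 64800.0) / 2345.19020227756) ; 36000.0</expression>
        </toolspecific>
      </place>
      <place id="IR">
        <name>
          <text>IR</text>
        </name>
        <initialMarking>
          <text>540</text>
        </initialMarking>
      </place>
      <place id="IR_I">
        <name>
          <text>IR_I</text>
        </name>
      </place>
      <place id="IR_I_P">
        <name>
          <text>IR_I_P</text>
        </name>
      </place>
      <place id="IR_I_P_Int">
        <name>
          <text>IR_I_P_Int</text>
        </name>
      </place>
      <place id="IR_Int">
        <name>
          <text>IR_Int</text>
        </name>
        <initialMarking>
          <text>60</text>
        </initialMarking>
      </place>
      <transition id="Bind_Insulin">
        <name>
          <text>Bind_Insulin</text>
        </name>
      </transition>
      <transition id="Diss_Insulin">
        <name>
          <text>Diss_Insulin</text>
        </name>
      </transition>
      <transition id="Inter_IR">
        <name>
          <text>Inter_IR</text>
        </name>
      </transition>
      <transition id="Phos_IR_I">
        <name>
          <text>Phos_IR_I</text>
        </name>
      </transition>
      <transition id="Dephos_IR_I_P">
        <name>
          <text>Dephos_IR_I_P</text>
        </name>
      </transition>
      <transition id="Inter_IR_I_P">
        <name>
          <text>Inter_IR_I_P</text>
        </name>
      </transition>
      <transition id="Deinter_IR_I_P">
        <name>
          <text>Deinter_IR_I_P</text>
        </name>
      </transition>
      <transition id="Dephos_IR_I_P_Int">
        <name>
          <text>Dephos_IR_I_P_Int</text>
        </name>
      </transition>
      <transition id="Deinter_IR">
        <name>
          <text>Deinter_IR</text>
        </name>
      </transition>
      <transition id="Degradation">
        <name>
          <text>Degradation</text>
        </name>
      </transition>
      <transition id="Synthesis">
        <name>
          <text>Synthesis</text>
        </name>
      </transition>
      <arc id="a0" source="Insulin" target="Bind_Insulin" />
      <arc id="a1" source="IR" target="Bind_Insulin" />
      <arc id="a2" source="Bind_Insulin" target="IR_I" />
      <arc id="a3" source="IR_I" target="Diss_Insulin" />
      <arc id="a4" source="Diss_Insulin" target="IR" />
      <arc id="a5" source="IR" target="Inter_IR" />
      <arc id="a6" source="Inter_IR" target="IR_Int" />
      <arc id="a7" source="IR_I" target="Phos_IR_I" />
      <arc id="a8" source="Phos_IR_I" target="IR_I_P" />
      <arc id="a9" source="IR_I_P" target="Dephos_IR_I_P" />
      <arc id="a10" source="Dephos_IR_I_P" target="IR_I" />
      <arc id="a11" source="IR_I_P" target="Inter_IR_I_P" />
      <arc id="a12" source="Inter_IR_I_P" target="IR_I_P_Int" />
      <arc id="a13" source="IR_I_P_Int" target="Deinter_IR_I_P" />
      <arc id="a14" source="Deinter_IR_I_P" target="IR_I_P" />
      <arc id="a15" source="IR_I_P_Int" target="Dephos_IR_I_P_Int" />
      <arc id="a16" source="Dephos_IR_I_P_Int" target="IR_Int" />
      <arc id="a17" source="IR_Int" target="Deinter_IR" />
      <arc id="a18" source="Deinter_IR" target="IR" />
      <arc id="a19" source="IR_Int" target="Degradation" />
      <arc id="a20" source="Synthesis" target="IR_Int" />
    </page>
  </net>
</pnml>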